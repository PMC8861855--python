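"""Grouped multi-view data container with explicit missingness.

A *group* (or modality) is a block of variables measured on the same N
samples, stored in the ``Dm x N`` orientation (variables in rows, samples
in columns) used throughout the model equations. Missing cells are carried
as an explicit boolean mask (``True`` = observed); the numeric value stored
under a masked cell is ignored by every downstream computation, which lets
removal operators keep the original value in place as hold-out truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GroupedDataset",
    "Hyperparameters",
    "standardise",
    "split",
    "load_csv",
    "save_csv",
    "load_hdf5",
    "save_hdf5",
]


@dataclass
class GroupedDataset:
    """M co-registered data matrices over common samples, with masks.

    Parameters
    ----------
    groups : list of ndarray, each ``(Dm, N)``
        One numeric matrix per group; all share the same sample ordering.
    masks : list of ndarray of bool, same shapes
        ``True`` marks an observed cell. Defaults to fully observed.
    sample_ids : ndarray of str, shape ``(N,)``
    variable_ids : list of ndarray of str, per-group ``(Dm,)``
    """

    groups: list
    masks: list = None
    sample_ids: np.ndarray = None
    variable_ids: list = None

    def __post_init__(self):
        self.groups = [np.asarray(g, dtype=float) for g in self.groups]
        if not self.groups:
            raise ValueError("at least one group is required")
        n = self.groups[0].shape[1]
        if self.masks is None:
            self.masks = [~np.isnan(g) for g in self.groups]
        else:
            self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
        if self.variable_ids is None:
            self.variable_ids = [
                np.array([f"g{m}_v{j}" for j in range(g.shape[0])])
                for m, g in enumerate(self.groups)
            ]
        else:
            self.variable_ids = [np.asarray(v) for v in self.variable_ids]
        self.validate()

    # -- basic properties -------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_samples(self) -> int:
        return self.groups[0].shape[1]

    @property
    def n_variables(self):
        return [g.shape[0] for g in self.groups]

    def validate(self, require_variable_coverage: bool = False) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        n = self.n_samples
        for m, (g, msk, vids) in enumerate(
            zip(self.groups, self.masks, self.variable_ids)
        ):
            if g.ndim != 2 or g.shape[1] != n:
                raise ValueError(f"group {m}: expected (Dm, {n}) matrix, got {g.shape}")
            if msk.shape != g.shape:
                raise ValueError(f"group {m}: mask shape {msk.shape} != data {g.shape}")
            if len(vids) != g.shape[0]:
                raise ValueError(f"group {m}: {len(vids)} variable ids for {g.shape[0]} rows")
            if np.any(np.isnan(g[msk])):
                raise ValueError(f"group {m}: NaN under an observed (mask=True) cell")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} samples")
        observed_any = np.zeros(n, dtype=bool)
        for msk in self.masks:
            observed_any |= msk.any(axis=0)
        if not observed_any.all():
            bad = self.sample_ids[~observed_any]
            raise ValueError(
                f"samples with no observed variable in any group: {list(bad[:5])}"
            )
        if require_variable_coverage:
            self.check_variable_coverage()

    def check_variable_coverage(self, min_observed: int = 1) -> None:
        """Error if any variable has fewer than ``min_observed`` observed cells."""
        for m, msk in enumerate(self.masks):
            counts = msk.sum(axis=1)
            bad = counts < min_observed
            if bad.any():
                names = list(self.variable_ids[m][bad][:5])
                raise ValueError(
                    f"group {m}: variables with <{min_observed} observed cells: {names}"
                )

    # -- convenience ------------------------------------------------------
    def observed_values(self, m: int) -> np.ndarray:
        """Flat array of the observed cell values of group ``m``."""
        return self.groups[m][self.masks[m]]

    def take_samples(self, idx) -> "GroupedDataset":
        """Sub-dataset restricted to the given sample indices (all groups)."""
        idx = np.asarray(idx)
        return GroupedDataset(
            groups=[g[:, idx] for g in self.groups],
            masks=[msk[:, idx] for msk in self.masks],
            sample_ids=self.sample_ids[idx],
            variable_ids=[v.copy() for v in self.variable_ids],
        )

    def copy(self) -> "GroupedDataset":
        return GroupedDataset(
            groups=[g.copy() for g in self.groups],
            masks=[m.copy() for m in self.masks],
            sample_ids=self.sample_ids.copy(),
            variable_ids=[v.copy() for v in self.variable_ids],
        )


@dataclass
class Hyperparameters:
    """Model hyperparameters: ARD/noise gamma priors, factor count, stopping rule.

    The gamma hyperparameters default to 1e-14, i.e. effectively
    uninformative priors on the loading precisions (alpha) and noise
    precisions (tau).
    """

    K: int = 15
    a_alpha: float = 1e-14
    b_alpha: float = 1e-14
    a_tau: float = 1e-14
    b_tau: float = 1e-14
    tol: float = 1e-6
    max_iter: int = 10000
    seed: int = 0

    def __post_init__(self):
        for name in ("a_alpha", "b_alpha", "a_tau", "b_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.tol <= 0:
            raise ValueError("tol must be strictly positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def standardise(data: GroupedDataset, reference: GroupedDataset | None = None):
    """Centre and scale each variable using observed-cell statistics.

    Statistics (mean and ddof-1 standard deviation over observed cells) are
    computed on ``reference`` — typically the training split — and applied
    to ``data``; masks are unchanged. With ``reference=None`` the data is
    its own reference.

    Raises
    ------
    ValueError
        If a reference variable has fewer than two observed cells or zero
        observed variance (the variable is named in the message).
    """
    if reference is None:
        reference = data
    new_groups = []
    for m in range(data.n_groups):
        ref_x, ref_mask = reference.groups[m], reference.masks[m]
        counts = ref_mask.sum(axis=1)
        if np.any(counts < 2):
            names = list(reference.variable_ids[m][counts < 2][:5])
            raise ValueError(f"group {m}: <2 observed reference values for {names}")
        xz = np.where(ref_mask, ref_x, 0.0)
        mean = xz.sum(axis=1) / counts
        sq = np.where(ref_mask, (ref_x - mean[:, None]) ** 2, 0.0)
        var = sq.sum(axis=1) / (counts - 1)
        zero = var <= 0
        if zero.any():
            names = list(reference.variable_ids[m][zero][:5])
            raise ValueError(f"group {m}: zero observed variance for {names}")
        sd = np.sqrt(var)
        new_groups.append((data.groups[m] - mean[:, None]) / sd[:, None])
    return GroupedDataset(
        groups=new_groups,
        masks=[m.copy() for m in data.masks],
        sample_ids=data.sample_ids.copy(),
        variable_ids=[v.copy() for v in data.variable_ids],
    )


def split(data: GroupedDataset, train_fraction: float, seed: int):
    """Sample-wise train/test partition, identical across groups.

    Returns ``(train, test)``. The train partition must leave every
    variable with at least one observed cell.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = data.n_samples
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    train = data.take_samples(train_idx)
    test = data.take_samples(test_idx)
    train.check_variable_coverage()
    return train, test


# ---------------------------------------------------------------------------
# I/O: delimited text (one CSV per group) and an HDF5 container
# ---------------------------------------------------------------------------

def save_csv(data: GroupedDataset, paths) -> None:
    """One CSV per group: header = sample ids, first column = variable ids.

    Masked cells are written as NaN (hold-out values under the mask are not
    representable in this format; use the HDF5 container to keep them).
    """
    if len(paths) != data.n_groups:
        raise ValueError("need one path per group")
    for m, path in enumerate(paths):
        x = np.where(data.masks[m], data.groups[m], np.nan)
        df = pd.DataFrame(x, index=data.variable_ids[m], columns=data.sample_ids)
        df.to_csv(path, float_format="%.17g")  # round-trips doubles exactly


def load_csv(paths, orientation: str = "variables_by_samples") -> GroupedDataset:
    """Read one CSV per group; NaN cells become mask=False.

    ``orientation='samples_by_variables'`` accepts transposed files and
    normalises them internally.
    """
    groups, masks, variable_ids = [], [], []
    sample_ids = None
    for path in paths:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if orientation == "samples_by_variables":
            df = df.T
        elif orientation != "variables_by_samples":
            raise ValueError(f"unknown orientation {orientation!r}")
        if sample_ids is None:
            sample_ids = df.columns.to_numpy(dtype=str)
        elif not np.array_equal(sample_ids, df.columns.to_numpy(dtype=str)):
            raise ValueError(f"{path}: sample ids differ from the first group's")
        x = df.to_numpy(dtype=float)
        mask = ~np.isnan(x)
        groups.append(np.where(mask, x, 0.0))
        masks.append(mask)
        variable_ids.append(df.index.to_numpy(dtype=str))
    return GroupedDataset(groups, masks, sample_ids, variable_ids)


def save_hdf5(data: GroupedDataset, path) -> None:
    """Binary container holding values (including masked hold-out truth) and masks."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["n_groups"] = data.n_groups
        f.create_dataset("sample_ids", data=np.asarray(data.sample_ids, dtype="S"))
        for m in range(data.n_groups):
            grp = f.create_group(f"group{m}")
            grp.create_dataset("values", data=data.groups[m])
            grp.create_dataset("mask", data=data.masks[m])
            grp.create_dataset(
                "variable_ids", data=np.asarray(data.variable_ids[m], dtype="S")
            )


def load_hdf5(path) -> GroupedDataset:
    import h5py

    with h5py.File(path, "r") as f:
        n_groups = int(f.attrs["n_groups"])
        sample_ids = f["sample_ids"][:].astype(str)
        groups, masks, variable_ids = [], [], []
        for m in range(n_groups):
            grp = f[f"group{m}"]
            groups.append(grp["values"][:])
            masks.append(grp["mask"][:].astype(bool))
            variable_ids.append(grp["variable_ids"][:].astype(str))
    return GroupedDataset(groups, masks, sample_ids, variable_ids)
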