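"""Structural connectome containers, I/O, thresholding and nodal summaries.

A connectome is a square symmetric matrix of nonnegative streamline counts
between parcels of a cortical parcellation.  Each parcel belongs to one of a
small number of large-scale functional networks (17 in the Schaefer
local-global scheme emulated here).  All downstream metrics (degree,
redundancy, average controllability) are computed on thresholded versions of
these matrices and aggregated to network means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    FormatError,
    ParameterError,
    ValidationError,
)

#: Network labels of the 17-network Schaefer local-global parcellation.
SCHAEFER17_LABELS: tuple[str, ...] = (
    "VisCent", "VisPeri", "SomMotA", "SomMotB",
    "DorsAttnA", "DorsAttnB", "SalVentAttnA", "SalVentAttnB",
    "LimbicA", "LimbicB", "ContA", "ContB", "ContC",
    "DefaultA", "DefaultB", "DefaultC", "TempPar",
)

_SYM_ATOL = 1e-8


@dataclass(frozen=True)
class Parcellation:
    """Mapping from parcels to large-scale network labels.

    Parameters
    ----------
    parcel_ids
        Ordered parcel identifiers (matrix row/column order).
    labels
        Network label of each parcel, aligned with ``parcel_ids``.
    """

    parcel_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.parcel_ids) != len(self.labels):
            raise ConfigurationError(
                f"{len(self.parcel_ids)} parcel ids but {len(self.labels)} labels"
            )
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ConfigurationError("duplicate parcel ids")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def networks(self) -> tuple[str, ...]:
        """Distinct network labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return tuple(seen)

    def members(self, network: str) -> np.ndarray:
        """Indices of the parcels belonging to ``network``."""
        idx = np.flatnonzero(np.asarray(self.labels) == network)
        if idx.size == 0:
            raise ConfigurationError(f"network {network!r} has no member parcels")
        return idx

    def sizes(self) -> dict[str, int]:
        return {net: int(self.members(net).size) for net in self.networks}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Parcellation":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["parcel_id", "network_label"]:
            raise FormatError(
                f"{path}: expected columns parcel_id, network_label, got {list(df.columns)}"
            )
        return cls(tuple(df["parcel_id"]), tuple(df["network_label"]))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"parcel_id": self.parcel_ids, "network_label": self.labels}
        ).to_csv(path, sep="\t", index=False)


def _check_weights(w: np.ndarray, parcellation: Parcellation) -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise FormatError(f"weights must be square, got shape {w.shape}")
    if w.shape[0] != parcellation.n_parcels:
        raise FormatError(
            f"matrix has {w.shape[0]} parcels but parcellation has "
            f"{parcellation.n_parcels}"
        )
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise FormatError(f"non-finite weight at ({i}, {j})")
    neg = np.argwhere(w < 0)
    if neg.size:
        i, j = neg[0]
        raise FormatError(f"negative weight {w[i, j]} at ({i}, {j})")
    asym = np.argwhere(np.abs(w - w.T) > _SYM_ATOL)
    if asym.size:
        i, j = asym[0]
        raise FormatError(
            f"asymmetric at ({i}, {j}): {w[i, j]} vs {w[j, i]}"
        )
    diag = np.argwhere(np.abs(np.diag(w)) > 0)
    if diag.size:
        i = int(diag[0][0])
        raise FormatError(f"nonzero diagonal entry {w[i, i]} at ({i}, {i})")


@dataclass
class Connectome:
    """One subject's weighted symmetric parcel-by-parcel adjacency.

    Symmetry, nonnegativity and a zero diagonal are enforced at construction;
    violations raise :class:`~ctrlred.errors.FormatError` naming the offending
    cell rather than being silently repaired.
    """

    weights: np.ndarray
    parcellation: Parcellation
    subject_id: str = ""
    threshold_fraction: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        _check_weights(self.weights, self.parcellation)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.weights, (0.0, 1.0)).all())

    def edge_count(self) -> int:
        """Number of undirected edges with nonzero weight."""
        return int(np.count_nonzero(self.weights) // 2)


@dataclass
class NodalMetrics:
    """A per-parcel metric vector for one subject (or a group average)."""

    subject_id: str
    name: str
    values: np.ndarray
    threshold_fraction: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("metric values must be a 1-d vector")


@dataclass
class NetworkSummary:
    """Per-network means of one nodal metric for one subject."""

    subject_id: str
    name: str
    means: pd.Series
    threshold_fraction: float | None = None


# ---------------------------------------------------------------------------
# I/O


def read_connectome(path: str | Path, parcellation: Parcellation,
                    subject_id: str | None = None) -> Connectome:
    """Read a tab-delimited square adjacency with parcel-id header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = tuple(str(c) for c in df.columns)
    if ids != parcellation.parcel_ids or tuple(str(i) for i in df.index) != parcellation.parcel_ids:
        raise FormatError(f"{path}: parcel ids do not match the parcellation")
    sid = subject_id if subject_id is not None else Path(path).stem
    return Connectome(df.to_numpy(dtype=float), parcellation, subject_id=sid)


def write_connectome(c: Connectome, path: str | Path) -> None:
    """Write the adjacency as a tab-delimited matrix (round-trips exactly)."""
    pd.DataFrame(
        c.weights, index=c.parcellation.parcel_ids, columns=c.parcellation.parcel_ids
    ).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Transforms


def threshold_connectome(c: Connectome, fraction: float,
                         scope: str = "global") -> Connectome:
    """Remove edges strictly below ``fraction`` of the maximum edge weight.

    The cutoff is subject-wise: ``fraction * max(weights)`` over the whole
    matrix (``scope="global"``, the default reading) or per network block
    (``scope="network"``, the alternative reading, where each within/between
    network block uses its own maximum).  Weights equal to the cutoff are
    kept.
    """
    if not (0.0 <= fraction < 1.0):
        raise ParameterError(f"fraction must be in [0, 1), got {fraction}")
    w = c.weights
    if not np.any(w > 0):
        raise DegenerateInputError("all-zero connectome cannot be thresholded")
    if scope == "global":
        cutoff = fraction * w.max()
        out = np.where(w < cutoff, 0.0, w)
    elif scope == "network":
        labels = np.asarray(c.parcellation.labels)
        out = w.copy()
        nets = c.parcellation.networks
        for a in nets:
            ia = c.parcellation.members(a)
            for b in nets:
                ib = c.parcellation.members(b)
                block = w[np.ix_(ia, ib)]
                mx = block.max()
                if mx > 0:
                    blk = np.where(block < fraction * mx, 0.0, block)
                    out[np.ix_(ia, ib)] = blk
        out = np.minimum(out, out.T)  # keep symmetry if block maxima differ
    else:
        raise ParameterError(f"unknown scope {scope!r}")
    return Connectome(out, c.parcellation, c.subject_id, threshold_fraction=fraction)


def binarize(c: Connectome) -> Connectome:
    """Map every nonzero weight to 1, preserving the edge support."""
    return Connectome(
        (c.weights > 0).astype(float), c.parcellation, c.subject_id,
        threshold_fraction=c.threshold_fraction,
    )


# ---------------------------------------------------------------------------
# Nodal summaries


def nodal_degree(c: Connectome) -> NodalMetrics:
    """Number of first-order (direct) neighbors of each node.

    Requires a binarized connectome; weighted input raises
    :class:`~ctrlred.errors.ValidationError`.
    """
    if not c.is_binary:
        raise ValidationError("nodal_degree requires a binarized connectome")
    return NodalMetrics(
        c.subject_id, "degree", c.weights.sum(axis=1),
        threshold_fraction=c.threshold_fraction,
    )


def network_means(m: NodalMetrics, parcellation: Parcellation) -> NetworkSummary:
    """Arithmetic mean of a nodal metric over the parcels of each network."""
    if m.values.size != parcellation.n_parcels:
        raise ConfigurationError(
            f"metric has {m.values.size} values, parcellation {parcellation.n_parcels}"
        )
    means = pd.Series(
        {net: float(m.values[parcellation.members(net)].mean())
         for net in parcellation.networks},
        name=m.name,
    )
    return NetworkSummary(m.subject_id, m.name, means, m.threshold_fraction)


def group_average_nodal(metrics: Sequence[NodalMetrics]) -> NodalMetrics:
    """Element-wise mean of a nodal metric across subjects."""
    if not metrics:
        raise ValidationError("empty metric list")
    n = metrics[0].values.size
    name = metrics[0].name
    for m in metrics:
        if m.values.size != n:
            raise ValidationError("mismatched parcel sets across subjects")
        if m.name != name:
            raise ValidationError(f"mixed metrics: {m.name!r} vs {name!r}")
    stack = np.vstack([m.values for m in metrics])
    return NodalMetrics(
        "group", name, stack.mean(axis=0),
        threshold_fraction=metrics[0].threshold_fraction,
    )


def make_block_parcellation(n_parcels: int, n_networks: int = 17) -> Parcellation:
    """Contiguous-block synthetic parcellation with Schaefer-style labels.

    Parcels are split into ``n_networks`` nearly equal contiguous groups; with
    17 networks the canonical Schaefer label names are used so synthetic runs
    read like real ones.
    """
    if n_networks < 1 or n_parcels < n_networks:
        raise ParameterError(
            f"need n_parcels >= n_networks >= 1, got {n_parcels}, {n_networks}"
        )
    if n_networks == 17:
        names = SCHAEFER17_LABELS
    else:
        names = tuple(f"Net{i + 1:02d}" for i in range(n_networks))
    sizes = np.full(n_networks, n_parcels // n_networks)
    sizes[: n_parcels % n_networks] += 1
    labels: list[str] = []
    for name, size in zip(names, sizes):
        labels.extend([name] * int(size))
    ids = tuple(f"P{i + 1:03d}" for i in range(n_parcels))
    return Parcellation(ids, tuple(labels))
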