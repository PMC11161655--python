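"""Average controllability from the controllability Gramian, and control hubs.

The structural network is treated as a discrete-time linear system
``x(t+1) = A x(t) + B_k u(t)`` with a single control node ``k``.  The
adjacency is first stabilized by dividing by one plus its spectral radius,
so the infinite-horizon controllability Gramian

    W_k = sum_{t=0}^inf  A^t B_k B_k' (A')^t

converges.  Average controllability of node ``k`` is ``trace(W_k)``; for a
symmetric stabilized adjacency this is the k-th diagonal entry of
``(I - A^2)^{-1}``, which is the closed form used by default.  A discrete
Lyapunov solve and a truncated power series are provided as independent
methods for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .connectome import Connectome, NodalMetrics, Parcellation
from .errors import (
    DegenerateInputError,
    DivergenceError,
    ParameterError,
    ValidationError,
)


@dataclass
class NormalizedAdjacency:
    """Spectrally normalized adjacency with radius strictly below one."""

    matrix: np.ndarray
    largest_abs_eigenvalue: float
    spectral_norm_applied: bool = True


@dataclass
class GramianResult:
    """Average controllability of one control node."""

    control_node: int
    average_controllability: float
    method: str
    truncation_terms: int | None = None


def normalize_adjacency(c: Connectome | np.ndarray) -> NormalizedAdjacency:
    """Divide the adjacency by one plus its largest-magnitude eigenvalue.

    For a symmetric matrix with spectral radius ``r`` the output has spectral
    radius ``r / (1 + r) < 1``, guaranteeing convergence of the Gramian
    series.
    """
    w = c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"adjacency must be square, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValidationError("adjacency contains non-finite entries")
    if not np.allclose(w, w.T, atol=1e-8):
        raise ValidationError("adjacency must be symmetric")
    lam = float(np.max(np.abs(linalg.eigvalsh(w)))) if w.size else 0.0
    return NormalizedAdjacency(w / (1.0 + lam), lam)


def _spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(linalg.eigvalsh(a)))) if a.size else 0.0


def average_controllability(
    a: NormalizedAdjacency | np.ndarray,
    method: str = "closed_form",
    truncation_terms: int = 1000,
) -> np.ndarray:
    """Average controllability of every node of a stabilized adjacency.

    Parameters
    ----------
    a
        Normalized adjacency (spectral radius < 1 required).
    method
        ``closed_form`` (diagonal of ``(I - A^2)^{-1}``), ``lyapunov``
        (per-node discrete Lyapunov solve) or ``truncated_sum`` (power
        series with ``truncation_terms`` terms).

    Returns
    -------
    numpy.ndarray
        Per-node values, all >= 1 (equality only for nodes isolated in
        ``A^2``).
    """
    A = a.matrix if isinstance(a, NormalizedAdjacency) else np.asarray(a, float)
    rho = _spectral_radius(A)
    if rho >= 1.0:
        raise DivergenceError(
            f"spectral radius {rho:.6f} >= 1: Gramian series diverges"
        )
    n = A.shape[0]
    if method == "closed_form":
        return np.diag(linalg.inv(np.eye(n) - A @ A)).copy()
    if method == "lyapunov":
        vals = np.empty(n)
        for k in range(n):
            Q = np.zeros((n, n))
            Q[k, k] = 1.0
            W = linalg.solve_discrete_lyapunov(A, Q)
            vals[k] = np.trace(W)
        return vals
    if method == "truncated_sum":
        if truncation_terms < 1:
            raise ParameterError("truncation_terms must be >= 1")
        P = A @ A
        term = np.eye(n)
        total = np.eye(n)
        for _ in range(truncation_terms):
            term = term @ P
            total += term
        return np.diag(total).copy()
    raise ParameterError(f"unknown method {method!r}")


def node_controllability(
    a: NormalizedAdjacency,
    control_node: int,
    method: str = "closed_form",
    truncation_terms: int = 1000,
) -> GramianResult:
    """Average controllability of a single control node."""
    vals = average_controllability(a, method=method, truncation_terms=truncation_terms)
    if not (0 <= control_node < vals.size):
        raise ParameterError(f"control node {control_node} out of range")
    return GramianResult(
        control_node, float(vals[control_node]), method,
        truncation_terms if method == "truncated_sum" else None,
    )


def nodal_average_controllability(c: Connectome) -> NodalMetrics:
    """Per-parcel average controllability of one subject's (weighted) connectome."""
    ac = average_controllability(normalize_adjacency(c))
    return NodalMetrics(
        c.subject_id, "average_controllability", ac,
        threshold_fraction=c.threshold_fraction,
    )


# ---------------------------------------------------------------------------
# Control hubs


@dataclass
class HubSet:
    """Control hubs of a group-level nodal controllability vector."""

    rule: str
    parameter: float
    hub_indices: tuple[int, ...]  # descending controllability, ties by index
    hub_ids: tuple[str, ...]
    values: tuple[float, ...]


def classify_hubs(
    group_ac: NodalMetrics,
    parcellation: Parcellation,
    rule: str = "mean_plus_sd",
    parameter: float = 1.0,
) -> HubSet:
    """Classify control hubs from group-averaged nodal controllability.

    ``mean_plus_sd``: nodes whose value exceeds the nodal mean plus
    ``parameter`` population standard deviations.  ``top_percent``: the
    ``ceil(parameter * n)`` highest-value nodes (``parameter`` is a fraction,
    e.g. 0.10 for the top decile).
    """
    if parameter <= 0:
        raise ParameterError(f"rule parameter must be > 0, got {parameter}")
    v = group_ac.values
    n = v.size
    if rule == "mean_plus_sd":
        thr = v.mean() + parameter * v.std(ddof=0)
        idx = np.flatnonzero(v > thr)
    elif rule == "top_percent":
        if parameter > 1:
            raise ParameterError("top_percent parameter is a fraction in (0, 1]")
        k = int(np.ceil(parameter * n))
        order = np.lexsort((np.arange(n), -v))
        idx = order[:k]
    else:
        raise ParameterError(f"unknown hub rule {rule!r}")
    order = np.lexsort((idx, -v[idx]))
    idx = idx[order]
    return HubSet(
        rule, float(parameter), tuple(int(i) for i in idx),
        tuple(parcellation.parcel_ids[i] for i in idx),
        tuple(float(v[i]) for i in idx),
    )


def hub_network_distribution(h: HubSet, parcellation: Parcellation) -> pd.Series:
    """Network-size-normalized hub percentages.

    Each network's hub count is divided by its size; the resulting densities
    are renormalized to sum to 100 so that a uniform hub density yields equal
    shares regardless of network size.
    """
    if not h.hub_indices:
        raise DegenerateInputError("empty hub set")
    labels = np.asarray(parcellation.labels)
    dens = {}
    for net in parcellation.networks:
        size = parcellation.members(net).size
        count = int(np.sum(labels[list(h.hub_indices)] == net))
        dens[net] = count / size
    total = sum(dens.values())
    return pd.Series({net: 100.0 * d / total for net, d in dens.items()},
                     name="hub_percent")
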