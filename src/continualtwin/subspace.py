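"""Hidden-layer geometry: dimensionality and principal angles.

Because the network is linear and inputs are one-hot, the hidden activity
for stimulus *i* is simply column *i* of the embedding matrix; the stimulus
by hidden-unit activation matrix is therefore a transposed column slice of
the embedding weights.

Two measures characterise what training did to this geometry:

- the number of principal components needed to capture 99% of the
  (centred) activation variance over all inputs — rich networks hold both
  tasks in a single 2-D subspace unless the rules are far apart, in which
  case the dimensionality doubles;
- the first principal angle between the top-2 PCA subspaces of the two
  tasks' stimuli, from the SVD of the inner-product matrix of their
  orthonormal bases: 0 deg means the tasks share a subspace, 90 deg means
  they are orthogonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .network import NetworkState

__all__ = [
    "hidden_activations",
    "n_components_99",
    "task_subspace",
    "principal_angle",
    "principal_angles",
    "SubspaceReport",
    "subspace_report",
]

VARIANCE_TARGET = 0.99


def hidden_activations(state_or_embed, stimulus_ids) -> np.ndarray:
    """Rows of hidden activity for one-hot inputs (stimuli x hidden units)."""
    W = state_or_embed.W_embed if isinstance(state_or_embed, NetworkState) else np.asarray(state_or_embed)
    ids = np.asarray(stimulus_ids, dtype=int)
    if np.any((ids < 0) | (ids >= W.shape[1])):
        raise ValueError("stimulus id out of range for this embedding")
    return W[:, ids].T


def n_components_99(acts: np.ndarray, variance_target: float = VARIANCE_TARGET) -> int:
    """Smallest k whose centred principal components reach the variance target."""
    acts = np.asarray(acts, dtype=float)
    if acts.shape[0] < 2:
        raise ValueError("need at least two activation rows")
    centred = acts - acts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    var = sv**2
    total = var.sum()
    if total == 0.0:
        return 0
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, variance_target - 1e-12) + 1)


def task_subspace(acts: np.ndarray, k: int = 2) -> np.ndarray:
    """Top-k principal directions of one task's activations (k x hidden).

    Rows are orthonormal.  Rank-deficient activations (fewer than k
    directions of variance) are flagged with a warning: the trailing
    directions are then arbitrary within numerical precision.
    """
    acts = np.asarray(acts, dtype=float)
    if acts.shape[0] < k + 1:
        raise ValueError(f"need more than {k} rows to identify a {k}-dimensional subspace")
    pca = PCA(n_components=k)
    pca.fit(acts)
    sv = pca.singular_values_
    if sv[0] == 0 or sv[-1] / sv[0] < 1e-12:
        warnings.warn("activations have rank < %d; trailing subspace directions are arbitrary" % k)
    return pca.components_


def _check_orthonormal(V: np.ndarray, name: str):
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError(f"{name} must be a k x d basis matrix")
    gram = V @ V.T
    if not np.allclose(gram, np.eye(V.shape[0]), atol=1e-6):
        raise ValueError(f"{name} rows are not orthonormal")
    return V


def principal_angles(V_a: np.ndarray, V_b: np.ndarray) -> np.ndarray:
    """All principal angles (degrees, ascending) between two subspaces.

    Computed from the singular values of V_a V_b^T, whose diagonal entries
    are the cosines of the principal angles.
    """
    V_a = _check_orthonormal(V_a, "V_a")
    V_b = _check_orthonormal(V_b, "V_b")
    if V_a.shape[1] != V_b.shape[1]:
        raise ValueError("bases must share an ambient dimension")
    s = np.linalg.svd(V_a @ V_b.T, compute_uv=False)
    return np.degrees(np.arccos(np.clip(s, -1.0, 1.0)))


def principal_angle(V_a: np.ndarray, V_b: np.ndarray) -> float:
    """First (smallest) principal angle, arccos of the largest singular value."""
    return float(principal_angles(V_a, V_b)[0])


@dataclass
class SubspaceReport:
    """Geometry summary for one trained network."""

    n99_after_A: int
    n99_after_B: int
    principal_angle_deg: float
    second_angle_deg: float
    basis_A: np.ndarray
    basis_B: np.ndarray


def subspace_report(results, n_stimuli: int = 6) -> SubspaceReport:
    """Full geometry report from a :class:`~.network.TrainingResults`.

    Dimensionality is measured over all 12 inputs after task A training and
    after task B training; the principal angle compares the top-2 subspaces
    of the two tasks' stimuli after task B training (the end-state geometry
    that determines retest behaviour).
    """
    after_a = results.phase_states["trainA"]
    after_b = results.phase_states["trainB"]
    all_ids = np.arange(2 * n_stimuli)
    n99_a = n_components_99(hidden_activations(after_a, all_ids))
    n99_b = n_components_99(hidden_activations(after_b, all_ids))
    basis_a = task_subspace(hidden_activations(after_b, np.arange(n_stimuli)))
    basis_b = task_subspace(hidden_activations(after_b, np.arange(n_stimuli, 2 * n_stimuli)))
    angles = principal_angles(basis_a, basis_b)
    return SubspaceReport(
        n99_after_A=n99_a,
        n99_after_B=n99_b,
        principal_angle_deg=float(angles[0]),
        second_angle_deg=float(angles[1]),
        basis_A=basis_a,
        basis_B=basis_b,
    )
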