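"""Generalized Procrustes Analysis with sliding semilandmarks.

Configurations are centred, scaled to unit centroid size and rotated onto an
iteratively refined consensus.  Semilandmarks then slide along the tangent of
the outline chord defined by their neighbours; the slide amounts minimise
either the thin-plate-spline bending energy of the deviation from the
consensus (default) or its Procrustes distance.  Superimposition and sliding
alternate until the consensus stabilises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core_data import LandmarkSet


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks from their
    centroid."""
    c = config - config.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


@dataclass
class AlignedShapes:
    sample_ids: list[str]
    aligned: np.ndarray  # (n, p, 2), unit centroid size
    centroid_sizes: np.ndarray  # recorded before scaling
    consensus: np.ndarray  # (p, 2)
    slider_spec: list[tuple[int, int, int]]

    @property
    def log_cs(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    @property
    def shape_variables(self) -> np.ndarray:
        """Procrustes residuals projected into the tangent space at the
        consensus, flattened to (n, 2p).

        Projection removes the size and rotation directions that
        superimposition only cancels to first order, so the effective
        dimensionality is at most 2p - 4 (translations, rotation and size
        removed), i.e. 52 for the 28-landmark scheme.
        """
        n = self.aligned.shape[0]
        res = (self.aligned - self.consensus).reshape(n, -1)
        c = self.consensus.reshape(-1)
        c = c / np.linalg.norm(c)
        rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])
        t = (self.consensus @ rot90).reshape(-1)
        t = t - (t @ c) * c
        t /= np.linalg.norm(t)
        res -= np.outer(res @ c, c)
        res -= np.outer(res @ t, t)
        return res

    def subset(self, idx) -> "AlignedShapes":
        idx = np.asarray(idx)
        return AlignedShapes(
            sample_ids=[self.sample_ids[i] for i in idx],
            aligned=self.aligned[idx],
            centroid_sizes=self.centroid_sizes[idx],
            consensus=self.consensus,
            slider_spec=self.slider_spec,
        )


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) minimising ||x R - target||."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _center_scale(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=0)
    return c / np.sqrt((c**2).sum())


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending energy matrix of a 2-D reference (p x p)."""
    p = reference.shape[0]
    d2 = ((reference[:, None, :] - reference[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.column_stack([np.ones(p), reference])
    L = np.zeros((p + 3, p + 3))
    L[:p, :p] = K
    L[:p, p:] = Q
    L[p:, :p] = Q.T
    Linv = np.linalg.pinv(L)
    return Linv[:p, :p]


def _slide(
    x: np.ndarray,
    consensus: np.ndarray,
    slider_spec: list[tuple[int, int, int]],
    energy: np.ndarray | None,
) -> np.ndarray:
    """Slide semilandmarks of one configuration along their chord tangents.

    ``energy=None`` uses the Procrustes-distance criterion (plain tangent
    projection); otherwise the bending-energy quadratic form is minimised.
    """
    p = x.shape[0]
    s = len(slider_spec)
    tangents = np.zeros((s, 2))
    idx = np.zeros(s, dtype=int)
    for k, (before, slider, after) in enumerate(slider_spec):
        t = x[after] - x[before]
        norm = np.linalg.norm(t)
        tangents[k] = t / norm if norm > 0 else 0.0
        idx[k] = slider
    dev = (x - consensus).reshape(-1, order="F")  # all x coords then all y
    U = np.zeros((2 * p, s))
    U[idx, np.arange(s)] = tangents[:, 0]
    U[p + idx, np.arange(s)] = tangents[:, 1]
    if energy is None:
        d = -(U.T @ dev)  # U has orthonormal columns (distinct landmarks)
    else:
        E2 = np.zeros((2 * p, 2 * p))
        E2[:p, :p] = energy
        E2[p:, p:] = energy
        A = U.T @ E2 @ U
        b = U.T @ E2 @ dev
        d = -np.linalg.pinv(A) @ b
    out = x.copy()
    out[idx] += d[:, None] * tangents
    return out


def gpa_align(
    lms: LandmarkSet,
    slide: bool = True,
    criterion: str = "bending_energy",
    tol: float = 1e-8,
    max_iter: int = 10,
) -> AlignedShapes:
    """Superimpose a landmark set; returns aligned shapes and centroid sizes.

    ``criterion`` is ``"bending_energy"`` (default) or ``"procrustes"``.
    Raises on degenerate (zero centroid size) configurations, naming the
    sample.
    """
    if criterion not in ("bending_energy", "procrustes"):
        raise ValueError(f"unknown sliding criterion {criterion!r}")
    X = np.asarray(lms.configurations, dtype=float).copy()
    n, p, _ = X.shape
    cs = np.empty(n)
    for i in range(n):
        cs[i] = centroid_size(X[i])
        if cs[i] <= 0:
            raise ValueError(f"degenerate configuration (zero centroid size): "
                             f"{lms.sample_ids[i]!r}")
        X[i] = _center_scale(X[i])

    consensus = X[0].copy()
    for _ in range(max_iter):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        if slide and lms.slider_spec:
            energy = (
                bending_energy_matrix(consensus)
                if criterion == "bending_energy"
                else None
            )
            for i in range(n):
                X[i] = _center_scale(
                    _slide(X[i], consensus, lms.slider_spec, energy)
                )
                X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new_consensus = _center_scale(X.mean(axis=0))
        delta = np.abs(new_consensus - consensus).max()
        consensus = new_consensus
        if delta < tol:
            break
    for i in range(n):  # final pass against the converged consensus
        X[i] = X[i] @ _optimal_rotation(X[i], consensus)
    return AlignedShapes(
        sample_ids=list(lms.sample_ids),
        aligned=X,
        centroid_sizes=cs,
        consensus=consensus,
        slider_spec=list(lms.slider_spec),
    )


def align_to_reference(
    lms: LandmarkSet,
    reference: AlignedShapes,
    slide: bool = True,
    criterion: str = "bending_energy",
) -> AlignedShapes:
    """Project new configurations into an existing alignment's frame.

    The reference consensus is left untouched, so shapes become comparable
    with the shape variables of the training alignment (used when scoring
    sympatric individuals against a discriminant function built on
    allopatric references).
    """
    X = np.asarray(lms.configurations, dtype=float).copy()
    n = X.shape[0]
    cs = np.empty(n)
    consensus = reference.consensus
    energy = None
    if slide and reference.slider_spec and criterion == "bending_energy":
        energy = bending_energy_matrix(consensus)
    for i in range(n):
        cs[i] = centroid_size(X[i])
        if cs[i] <= 0:
            raise ValueError(f"degenerate configuration (zero centroid size): "
                             f"{lms.sample_ids[i]!r}")
        x = _center_scale(X[i])
        x = x @ _optimal_rotation(x, consensus)
        if slide and reference.slider_spec:
            x = _center_scale(_slide(x, consensus, reference.slider_spec, energy))
            x = x @ _optimal_rotation(x, consensus)
        X[i] = x
    return AlignedShapes(
        sample_ids=list(lms.sample_ids),
        aligned=X,
        centroid_sizes=cs,
        consensus=consensus,
        slider_spec=list(reference.slider_spec),
    )
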