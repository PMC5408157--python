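"""Rigid-body geometry: least-squares superposition and RMSD.

The closed-form Kabsch solution is used everywhere a rigid alignment is
needed (conformer deduplication, ligand-onto-hypothesis alignment), so the
whole package shares a single, well-tested primitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform", "kabsch", "rmsd", "superposed_rmsd"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping source onto target coordinates."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    Both arrays are (n, 3) with matched row ordering, n >= 1. Reflections are
    excluded: the returned rotation is always proper (det = +1).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError(
            f"coordinate shape mismatch: {source.shape} vs {target.shape}"
        )
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (source - mu_s).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=mu_t - rot @ mu_s)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (non-superposed) root-mean-square deviation between point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between point sets over all rigid superpositions."""
    t = kabsch(a, b)
    return rmsd(t.apply(np.asarray(a, dtype=float)), b)
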