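"""Container for Gaussian mixture parameters with covariance decomposition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomposition import compose_batch, decompose_scatter


@dataclass
class MixtureParameters:
    """Parameters ``(pi_j, mu_j, Sigma_j)`` of a k-component Gaussian mixture.

    The derived decomposition ``Sigma_j = volumes[j] * R_j diag(shapes[j]) R_j'``
    is attached lazily; ``shapes`` stores the diagonal vectors.
    """

    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, p)
    covariances: np.ndarray  # (k, p, p)
    volumes: np.ndarray | None = field(default=None)  # (k,)
    shapes: np.ndarray | None = field(default=None)  # (k, p)
    rotations: np.ndarray | None = field(default=None)  # (k, p, p)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        k, p = self.means.shape
        if self.weights.shape != (k,) or self.covariances.shape != (k, p, p):
            raise ValueError("inconsistent parameter shapes")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be positive and sum to one")

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    @classmethod
    def from_decomposition(cls, weights, means, volumes, shapes, rotations) -> "MixtureParameters":
        volumes = np.asarray(volumes, dtype=float)
        shapes = np.asarray(shapes, dtype=float)
        rotations = np.asarray(rotations, dtype=float)
        covs = compose_batch(volumes, shapes, rotations)
        return cls(
            weights=weights,
            means=means,
            covariances=covs,
            volumes=volumes,
            shapes=shapes,
            rotations=rotations,
        )

    def with_decomposition(self, rotation: str = "V") -> "MixtureParameters":
        """Return self with the per-component decomposition populated.

        Under the axis-aligned regime ("I") the shape keeps the original
        coordinate order (the covariances must be diagonal); otherwise each
        covariance is eigendecomposed with non-increasing shape elements.
        """
        if self.volumes is not None:
            return self
        k, p = self.means.shape
        vols = np.empty(k)
        shapes = np.empty((k, p))
        rots = np.empty((k, p, p))
        for j in range(k):
            C = self.covariances[j]
            if rotation == "I":
                if not np.allclose(C, np.diag(np.diag(C)), atol=1e-8 * np.abs(C).max()):
                    raise ValueError(
                        "axis-aligned decomposition requires diagonal covariances"
                    )
                diag = np.diag(C)
                vols[j] = float(np.exp(np.mean(np.log(diag))))
                shapes[j] = diag / vols[j]
                rots[j] = np.eye(p)
            else:
                vols[j], shapes[j], rots[j] = decompose_scatter(C, rotation)
        self.volumes, self.shapes, self.rotations = vols, shapes, rots
        return self

    def to_dict(self) -> dict:
        self.with_decomposition()
        return {
            "k": int(self.n_components),
            "p": int(self.n_features),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "scatters": self.covariances.tolist(),
            "decomposition": {
                "volumes": self.volumes.tolist(),
                "shapes": self.shapes.tolist(),
                "rotations": self.rotations.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParameters":
        dec = d.get("decomposition") or {}
        return cls(
            weights=np.array(d["weights"], dtype=float),
            means=np.array(d["means"], dtype=float),
            covariances=np.array(d["scatters"], dtype=float),
            volumes=np.array(dec["volumes"], dtype=float) if dec else None,
            shapes=np.array(dec["shapes"], dtype=float) if dec else None,
            rotations=np.array(dec["rotations"], dtype=float) if dec else None,
        )
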