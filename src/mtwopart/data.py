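"""Core data containers for clustered semicontinuous outcomes.

A semicontinuous outcome is nonnegative with a point mass at exactly zero
and a right-skewed continuous distribution on the positive reals (e.g.,
deaths per 100 confirmed cases across countries, clustered by region).
The containers here carry the outcome, the cluster labels, and separate
design matrices for the zero (binary) part and the continuous part.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Family(str, enum.Enum):
    """Distribution of the positive part: log-normal or beta prime."""

    LN = "LN"
    BP = "BP"


@dataclass(frozen=True)
class ModelSpec:
    """What model to fit: family, marginalized vs conventional, covariates.

    Both parts always include an intercept; the two parts may share
    covariates or use completely different ones.
    """

    family: Family = Family.LN
    marginalized: bool = True
    zero_covariates: tuple[str, ...] = ()
    cont_covariates: tuple[str, ...] = ()
    cluster_column: str = "cluster"

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "zero_covariates", tuple(self.zero_covariates))
        object.__setattr__(self, "cont_covariates", tuple(self.cont_covariates))


@dataclass
class ParameterSet:
    """Model parameters on the natural scale.

    alpha : zero-part coefficients (log-odds of a positive outcome).
    beta : continuous-part coefficients (log marginal mean for the
        marginalized model; log conditional mean for the conventional one).
    dispersion : sigma (log-scale SD) for the LN family, or the precision
        phi for the BP family. Strictly positive.
    sd_b1, sd_b2 : SDs of the independent cluster random intercepts of the
        zero and continuous parts. Nonnegative; zero switches the
        likelihood to the plug-in (no random effect) path.
    """

    alpha: np.ndarray
    beta: np.ndarray
    dispersion: float
    sd_b1: float = 0.0
    sd_b2: float = 0.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if not self.dispersion > 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if self.sd_b1 < 0 or self.sd_b2 < 0:
            raise ValueError("random-intercept SDs must be nonnegative")

    # -- flat internal vector used by the optimizer (unconstrained scale) --
    _SD_FLOOR = 1e-8

    def to_internal(self) -> np.ndarray:
        return np.concatenate(
            [
                self.alpha,
                self.beta,
                [np.log(self.dispersion)],
                [np.log(max(self.sd_b1, self._SD_FLOOR))],
                [np.log(max(self.sd_b2, self._SD_FLOOR))],
            ]
        )

    @classmethod
    def from_internal(cls, theta: np.ndarray, n_alpha: int, n_beta: int) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        if theta.size != n_alpha + n_beta + 3:
            raise ValueError("internal parameter vector has wrong length")
        a = theta[:n_alpha]
        b = theta[n_alpha : n_alpha + n_beta]
        disp, s1, s2 = np.exp(theta[n_alpha + n_beta :])
        return cls(a, b, float(disp), float(s1), float(s2))

    def names(self, zero_names: list[str], cont_names: list[str], family: Family) -> list[str]:
        disp = "sigma" if Family(family) is Family.LN else "phi"
        return (
            [f"zero:{n}" for n in zero_names]
            + [f"cont:{n}" for n in cont_names]
            + [disp, "sd_b1", "sd_b2"]
        )


@dataclass
class SemicontinuousDataset:
    """One row per observation: outcome, cluster label, per-part designs.

    ``Z`` and ``X`` carry a leading intercept column. ``psi`` is the
    nonzero indicator I(y > 0); zero means *exactly* zero — proportions
    such as 0.003 deaths per 100 cases stay in the continuous part.
    """

    y: np.ndarray
    cluster: np.ndarray
    Z: np.ndarray
    X: np.ndarray
    zero_names: list[str] = field(default_factory=lambda: ["intercept"])
    cont_names: list[str] = field(default_factory=lambda: ["intercept"])
    true_effects: pd.DataFrame | None = None  # simulator diagnostics (b1, b2 per cluster)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.cluster = np.asarray(self.cluster)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if np.any(self.y < 0):
            bad = int(np.flatnonzero(self.y < 0)[0])
            raise ValueError(f"negative outcome at row {bad}: y={self.y[bad]}")
        if not (self.cluster.size == n and self.Z.shape[0] == n and self.X.shape[0] == n):
            raise ValueError("y, cluster, Z and X must have one row per observation")
        if len(self.zero_names) != self.Z.shape[1] or len(self.cont_names) != self.X.shape[1]:
            raise ValueError("covariate name lists must match design matrix widths")

    @property
    def psi(self) -> np.ndarray:
        """Nonzero indicator; exact comparison against zero by design."""
        return (self.y > 0).astype(float)

    @property
    def n_obs(self) -> int:
        return int(self.y.size)

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.cluster)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_ids.size)

    def cluster_blocks(self) -> list["ClusterBlock"]:
        blocks = []
        for cid in self.cluster_ids:
            idx = np.flatnonzero(self.cluster == cid)
            blocks.append(
                ClusterBlock(
                    cluster_id=cid,
                    y=self.y[idx],
                    Z=self.Z[idx],
                    X=self.X[idx],
                )
            )
        return blocks

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        cluster: str,
        zero_covariates: tuple[str, ...] | list[str] = (),
        cont_covariates: tuple[str, ...] | list[str] = (),
    ) -> "SemicontinuousDataset":
        for col in [outcome, cluster, *zero_covariates, *cont_covariates]:
            if col not in df.columns:
                raise KeyError(f"column {col!r} not found in input data")
        n = len(df)
        Z = np.column_stack([np.ones(n)] + [df[c].to_numpy(float) for c in zero_covariates])
        X = np.column_stack([np.ones(n)] + [df[c].to_numpy(float) for c in cont_covariates])
        return cls(
            y=df[outcome].to_numpy(float),
            cluster=df[cluster].astype(str).to_numpy(),
            Z=Z,
            X=X,
            zero_names=["intercept", *zero_covariates],
            cont_names=["intercept", *cont_covariates],
        )

    def to_dataframe(self, outcome: str = "y", cluster: str = "cluster") -> pd.DataFrame:
        out = {outcome: self.y, cluster: self.cluster}
        for j, name in enumerate(self.zero_names[1:], start=1):
            out[name] = self.Z[:, j]
        for j, name in enumerate(self.cont_names[1:], start=1):
            if name not in out:
                out[name] = self.X[:, j]
        return pd.DataFrame(out)


@dataclass
class ClusterBlock:
    """All observations sharing one cluster label."""

    cluster_id: object
    y: np.ndarray
    Z: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.size == 0:
            raise ValueError(f"cluster {self.cluster_id!r} has no observations")

    @property
    def psi(self) -> np.ndarray:
        return (self.y > 0).astype(float)

    @property
    def n_obs(self) -> int:
        return int(self.y.size)
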