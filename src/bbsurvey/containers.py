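"""Data containers: survey count matrices and generative parameter sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ConsumptionMatrix", "RegionParams", "read_survey", "write_survey"]


@dataclass
class ConsumptionMatrix:
    """One region's survey: n households x J food groups of weekly day counts.

    ``counts[i, j]`` is the number of days (0..m) in the recall window on
    which household ``i`` consumed food group ``j``.
    """

    counts: np.ndarray
    group_names: list[str]
    region: str = "region"
    household_ids: np.ndarray | None = None
    m: int = 7

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array (households x groups)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers (day counts)")
            self.counts = self.counts.astype(np.int64)
        n, j = self.counts.shape
        if n < 1:
            raise ValueError("need at least one household")
        if j != len(self.group_names):
            raise ValueError("group_names length does not match count columns")
        if np.any(self.counts < 0) or np.any(self.counts > self.m):
            raise ValueError(f"counts must lie in [0, {self.m}]")
        if self.household_ids is None:
            self.household_ids = np.arange(n)
        else:
            self.household_ids = np.asarray(self.household_ids)
            if len(self.household_ids) != n:
                raise ValueError("household_ids length mismatch")

    @property
    def n_households(self) -> int:
        return self.counts.shape[0]

    @property
    def n_groups(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.group_names)
        df.insert(0, "household_id", self.household_ids)
        df.insert(0, "region", self.region)
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, group_names: list[str] | None = None,
        region: str | None = None, m: int = 7,
    ) -> "ConsumptionMatrix":
        reserved = {"region", "household_id"}
        if group_names is None:
            group_names = [c for c in df.columns if c not in reserved]
        if region is None:
            region = str(df["region"].iloc[0]) if "region" in df else "region"
        ids = df["household_id"].to_numpy() if "household_id" in df else None
        return cls(
            counts=df[group_names].to_numpy(),
            group_names=list(group_names),
            region=region,
            household_ids=ids,
            m=m,
        )

    def subset_groups(self, names: list[str]) -> "ConsumptionMatrix":
        idx = [self.group_names.index(g) for g in names]
        return ConsumptionMatrix(
            counts=self.counts[:, idx],
            group_names=list(names),
            region=self.region,
            household_ids=self.household_ids,
            m=self.m,
        )


@dataclass
class RegionParams:
    """Full generative parameter set for one region.

    Per food group: daily probability ``p``, dispersion ``theta``, and the
    random-effect standard deviation ``sigma``; plus the J x J correlation
    matrix ``Omega`` of the household random effects.  The implied covariance
    is ``Sigma = diag(sigma) @ Omega @ diag(sigma)``.
    """

    group_names: list[str]
    p: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray
    Omega: np.ndarray
    m: int = 7
    region: str = "region"

    def __post_init__(self) -> None:
        J = len(self.group_names)
        self.p = np.asarray(self.p, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.Omega = np.asarray(self.Omega, dtype=float)
        for name, arr in (("p", self.p), ("theta", self.theta), ("sigma", self.sigma)):
            if arr.shape != (J,):
                raise ValueError(f"{name} must have length {J}")
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("p entries must be in (0, 1)")
        if np.any(self.theta <= 0):
            raise ValueError("theta entries must be positive")
        if np.any(self.sigma < 0):
            raise ValueError("sigma entries must be non-negative")
        if self.Omega.shape != (J, J):
            raise ValueError(f"Omega must be {J}x{J}")
        if not np.allclose(self.Omega, self.Omega.T, atol=1e-10):
            raise ValueError("Omega must be symmetric")
        if not np.allclose(np.diag(self.Omega), 1.0, atol=1e-10):
            raise ValueError("Omega must have unit diagonal")
        if np.any(np.abs(self.Omega) > 1 + 1e-12):
            raise ValueError("Omega entries must lie in [-1, 1]")
        eigmin = np.linalg.eigvalsh(self.Omega).min()
        if eigmin < -1e-8:
            raise ValueError(f"Omega is not positive semi-definite (min eig {eigmin:.2e})")

    @property
    def J(self) -> int:
        return len(self.group_names)

    @property
    def Sigma(self) -> np.ndarray:
        D = np.diag(self.sigma)
        return D @ self.Omega @ D

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "m": self.m,
            "group_names": list(self.group_names),
            "p": self.p.tolist(),
            "theta": self.theta.tolist(),
            "sigma": self.sigma.tolist(),
            "Omega": self.Omega.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionParams":
        return cls(
            group_names=list(d["group_names"]),
            p=np.asarray(d["p"], dtype=float),
            theta=np.asarray(d["theta"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            Omega=np.asarray(d["Omega"], dtype=float),
            m=int(d.get("m", 7)),
            region=str(d.get("region", "region")),
        )


def read_survey(
    path, group_names: list[str] | None = None, region: str | None = None, m: int = 7,
) -> tuple[ConsumptionMatrix, int]:
    """Read and validate a survey CSV.

    Rows with missing, non-integer, or out-of-range counts are dropped with a
    logged reason.  Returns the validated matrix and the number of rejected
    rows.  Raises if declared group columns are absent or no valid row remains.
    """
    df = pd.read_csv(path)
    reserved = {"region", "household_id"}
    if group_names is None:
        group_names = [c for c in df.columns if c not in reserved]
    missing_cols = [g for g in group_names if g not in df.columns]
    if missing_cols:
        raise ValueError(f"survey file {path} lacks declared group columns: {missing_cols}")

    vals = df[group_names].apply(pd.to_numeric, errors="coerce")
    ok = vals.notna().all(axis=1)
    ok &= (vals.fillna(-1) == np.floor(vals.fillna(-1))).all(axis=1)
    ok &= ((vals >= 0) & (vals <= m)).all(axis=1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "read_survey: rejected %d row(s) with missing or out-of-range counts in %s",
            n_rejected, path,
        )
    kept = df.loc[ok].copy()
    if kept.empty:
        raise ValueError(f"no valid household rows in {path}")
    kept[group_names] = vals.loc[ok].astype(np.int64)
    matrix = ConsumptionMatrix.from_dataframe(
        kept, group_names=group_names, region=region, m=m
    )
    return matrix, n_rejected


def write_survey(matrix: ConsumptionMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, index=False)
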