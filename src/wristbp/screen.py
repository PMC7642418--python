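"""Training-set outlier exclusion: 3-sigma screen, then autoencoder screen.

Two passes, in fixed order:

1. univariate 3-sigma filter — a row is dropped if *any* feature lies
   outside mean +/- 3 SD (single-pass statistics over the input table);
2. an undercomplete autoencoder is fitted to the survivors and a row is
   dropped if its reconstruction MSE exceeds mean(MSE) + 3 SD(MSE)
   (one-sided: only poorly reconstructed rows are anomalous).

The autoencoder is linear (single undercomplete hidden layer, fitted in
closed form via the SVD — the global optimum of the linear reconstruction
objective).  Its job is to fail on rows that break the correlation
structure of the features even when every individual feature is in range.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "ScreenReport",
    "LinearAutoencoder",
    "three_sigma_filter",
    "fit_autoencoder",
    "autoencoder_filter",
    "screen_features",
]

ArrayLike = Union[np.ndarray, pd.DataFrame]


def _as_matrix(table: ArrayLike) -> np.ndarray:
    x = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("feature table must be 2-D")
    return x


@dataclass
class ScreenReport:
    """Bookkeeping for the two-stage screen; counts never increase."""

    n_input: int
    n_after_sigma: int
    n_after_autoencoder: Optional[int] = None
    excluded_ids: list = field(default_factory=list)
    sigma_bounds: Optional[pd.DataFrame] = None  # per-feature mean/sd
    ae_mse_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        chain = [self.n_input, self.n_after_sigma]
        if self.n_after_autoencoder is not None:
            chain.append(self.n_after_autoencoder)
        if any(a < b for a, b in zip(chain, chain[1:])) or chain[-1] < 0:
            raise ValueError(f"screen counts must be non-increasing, got {chain}")

    def to_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "n_after_sigma": self.n_after_sigma,
            "n_after_autoencoder": self.n_after_autoencoder,
            "excluded_ids": list(map(int, self.excluded_ids)),
            "ae_mse_threshold": self.ae_mse_threshold,
        }
        if self.sigma_bounds is not None:
            d["sigma_bounds"] = self.sigma_bounds.to_dict(orient="list")
        return d


def three_sigma_filter(table: ArrayLike) -> tuple[np.ndarray, ScreenReport]:
    """Retain rows whose every feature lies within mean +/- 3 SD.

    Statistics are computed over the input table in a single pass (no
    iterative re-screening).  Rows exactly on a 3-sigma boundary are
    retained; zero-variance features never trigger exclusion.
    """
    x = _as_matrix(table)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate sigma bounds")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    informative = sd > 0
    dev = np.abs(x - mean)
    within = np.ones_like(x, dtype=bool)
    within[:, informative] = dev[:, informative] <= 3.0 * sd[informative]
    mask = within.all(axis=1)
    cols = (
        list(table.columns)
        if isinstance(table, pd.DataFrame)
        else [f"f{i}" for i in range(x.shape[1])]
    )
    report = ScreenReport(
        n_input=x.shape[0],
        n_after_sigma=int(mask.sum()),
        excluded_ids=list(np.flatnonzero(~mask)),
        sigma_bounds=pd.DataFrame({"mean": mean, "sd": sd}, index=cols),
    )
    return mask, report


@dataclass(frozen=True)
class LinearAutoencoder:
    """Undercomplete linear autoencoder: encode = project onto the top
    ``bottleneck_dim`` principal directions, decode = re-embed + mean."""

    mean: np.ndarray          # (d,)
    components: np.ndarray    # (k, d), orthonormal rows
    bottleneck_dim: int
    n_features: int

    def encode(self, x: ArrayLike) -> np.ndarray:
        x = _as_matrix(x)
        self._check(x)
        return (x - self.mean) @ self.components.T

    def reconstruct(self, x: ArrayLike) -> np.ndarray:
        x = _as_matrix(x)
        self._check(x)
        return self.mean + (x - self.mean) @ self.components.T @ self.components

    def mse_per_row(self, x: ArrayLike) -> np.ndarray:
        """Mean over features of the squared reconstruction differences."""
        x = _as_matrix(x)
        return ((x - self.reconstruct(x)) ** 2).mean(axis=1)

    def _check(self, x: np.ndarray) -> None:
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"schema mismatch: autoencoder expects {self.n_features} features, got {x.shape[1]}"
            )


def fit_autoencoder(
    table: ArrayLike,
    bottleneck_dim: Optional[int] = None,
    seed: int = 0,
) -> LinearAutoencoder:
    """Fit the undercomplete autoencoder on retained rows.

    ``bottleneck_dim`` defaults to ceil(d/2); it must be strictly smaller
    than the feature dimension (the screen relies on the model being unable
    to reconstruct arbitrary rows).  The closed-form SVD fit is exactly
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    x = _as_matrix(table)
    n, d = x.shape
    k = bottleneck_dim if bottleneck_dim is not None else math.ceil(d / 2)
    if k >= d:
        raise ValueError(f"bottleneck_dim {k} must be < feature dim {d} (undercomplete)")
    if k < 1:
        raise ValueError("bottleneck_dim must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 rows to fit the autoencoder")
    mean = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - mean, full_matrices=False)
    comps = vt[:k]
    # Fix component signs for bit-reproducibility across BLAS builds.
    signs = np.sign(comps[np.arange(len(comps)), np.argmax(np.abs(comps), axis=1)])
    comps = comps * signs[:, None]
    return LinearAutoencoder(mean=mean, components=comps, bottleneck_dim=k, n_features=d)


def autoencoder_filter(
    table: ArrayLike,
    ae: LinearAutoencoder,
    prior: Optional[ScreenReport] = None,
) -> tuple[np.ndarray, ScreenReport]:
    """Drop rows whose reconstruction MSE exceeds mean + 3 SD of the MSEs.

    One-sided: unusually *good* reconstruction is never anomalous.  Rows
    exactly at the threshold are retained.
    """
    x = _as_matrix(table)
    mse = ae.mse_per_row(x)
    thr = float(mse.mean() + 3.0 * mse.std(ddof=1)) if len(mse) > 1 else float("inf")
    # Numerically-zero MSEs (perfectly reconstructable data) are never
    # anomalous, whatever their relative spread in float dust.
    thr = max(thr, 1e-12 * float(x.var()))
    mask = mse <= thr
    n_in = prior.n_input if prior is not None else x.shape[0]
    n_sigma = prior.n_after_sigma if prior is not None else x.shape[0]
    report = ScreenReport(
        n_input=n_in,
        n_after_sigma=n_sigma,
        n_after_autoencoder=int(mask.sum()),
        excluded_ids=(list(prior.excluded_ids) if prior is not None else [])
        + list(np.flatnonzero(~mask)),
        sigma_bounds=prior.sigma_bounds if prior is not None else None,
        ae_mse_threshold=thr,
    )
    return mask, report


def screen_features(
    table: pd.DataFrame,
    bottleneck_dim: Optional[int] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, ScreenReport]:
    """Full two-stage screen; the autoencoder is retrained on the rows that
    survive the sigma pass.  Returns (clean table, retained mask over the
    input rows, report)."""
    sigma_mask, sigma_report = three_sigma_filter(table)
    survivors = table.loc[sigma_mask]
    ae = fit_autoencoder(survivors, bottleneck_dim=bottleneck_dim, seed=seed)
    ae_mask_local, report = autoencoder_filter(survivors, ae, prior=sigma_report)
    # Map the autoencoder exclusions back to positions in the input table.
    survivor_pos = np.flatnonzero(sigma_mask)
    full_mask = sigma_mask.copy()
    full_mask[survivor_pos[~ae_mask_local]] = False
    report.excluded_ids = sorted(
        set(sigma_report.excluded_ids) | set(survivor_pos[~ae_mask_local])
    )
    return table.loc[full_mask], full_mask, report
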