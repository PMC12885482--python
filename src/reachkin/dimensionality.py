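"""Double-cross-validated PCA estimate of kinematic dimensionality.

The number of linearly independent degrees of freedom among the 24 joint
angles (or velocities) is estimated by holding out both observations and
variables: PCA is fit on a training subset of observations; for each
held-out observation, each variable in turn is hidden, the low-dimensional
coordinates are regressed from the remaining 23 variables and their
loadings, and the hidden variable is reconstructed from those coordinates.
The optimal dimensionality minimizes the mean held-out reconstruction
error over variables and observation partitions.  Unlike naive PCA
cross-validation, holding out variables prevents the trivial monotone
decrease of error with candidate rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CvPcaResult:
    """Held-out reconstruction error per candidate rank and the argmin."""

    candidates: np.ndarray
    errors: np.ndarray  # (n_candidates, n_partitions) mean squared error
    optimal_dimensionality: int
    skipped: list

    @property
    def mean_error(self) -> np.ndarray:
        return self.errors.mean(axis=1)

    def report(self) -> dict:
        return {
            "candidates": self.candidates.tolist(),
            "error_mean": self.mean_error.tolist(),
            "error_sd": self.errors.std(axis=1).tolist(),
            "optimal_dimensionality": int(self.optimal_dimensionality),
        }


def cv_pca_dimensionality(
    data: np.ndarray,
    candidates=None,
    n_partitions: int = 5,
    rng: np.random.Generator | int | None = None,
    test_fraction: float = 0.2,
    ridge: float = 1e-8,
) -> CvPcaResult:
    """Estimate the linear dimensionality of ``data`` (observations x p).

    Parameters
    ----------
    data : (n_obs, p)
        Concatenated angle (or velocity) samples; contact frames should be
        excluded upstream.  Mean-centering uses the training split.
    candidates : iterable of int
        Candidate dimensionalities; default ``1..p-1`` (a candidate equal
        to p cannot be identified from p-1 remaining variables and is
        rejected).
    n_partitions : int
        Random disjoint-test observation partitions (80/20 by default,
        re-randomized per repetition).
    ridge : float
        Tikhonov fallback for the coordinate regression conditioning.
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if candidates is None:
        candidates = np.arange(1, p)
    candidates = np.asarray(list(candidates), dtype=int)
    if np.any(candidates >= p) or np.any(candidates < 1):
        raise ValueError(f"candidates must lie in 1..{p - 1}")
    rng = np.random.default_rng(rng)

    errors = np.zeros((candidates.size, n_partitions))
    skipped: list = []
    n_test = max(1, int(round(test_fraction * n)))
    for part in range(n_partitions):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        xtr = x[train_idx]
        mu = xtr.mean(axis=0)
        xtr = xtr - mu
        xte = x[test_idx] - mu
        # PCA loadings from the training covariance
        _, s, vt = np.linalg.svd(xtr, full_matrices=False)
        if s[0] <= 0:
            skipped.append(("partition", part))
            errors[:, part] = np.nan
            continue
        for ci, d in enumerate(candidates):
            v = vt[:d].T  # (p, d) loadings
            se = 0.0
            for j in range(p):
                keep = np.arange(p) != j
                vk = v[keep]  # (p-1, d)
                # low-D coordinates of each test row from its other variables
                g = vk.T @ vk + ridge * np.eye(d)
                coords = np.linalg.solve(g, vk.T @ xte[:, keep].T)  # (d, n_test)
                recon = v[j] @ coords
                se += np.sum((xte[:, j] - recon) ** 2)
            errors[ci, part] = se / (xte.size)
    mean_err = np.nanmean(errors, axis=1)
    if not np.all(np.isfinite(mean_err)):
        raise ValueError("all partitions degenerate; cannot estimate dimensionality")
    best = int(candidates[int(np.argmin(mean_err))])
    return CvPcaResult(candidates=candidates, errors=errors,
                       optimal_dimensionality=best, skipped=skipped)
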