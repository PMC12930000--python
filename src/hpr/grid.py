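"""Evaluation grid for the horseshoe process.

The latent function is defined on the merged, strictly increasing sequence of
unique observed predictor values and any requested augmentation points.  Each
observation is tied to its gridpoint by an index map; increments of the
process live on the spacings between consecutive gridpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "build_grid"]


@dataclass(frozen=True)
class Grid:
    """Ordered evaluation grid shared by all model components.

    Attributes
    ----------
    t : ndarray, shape (m,)
        Strictly increasing gridpoint locations (unique observed predictor
        values merged with augmentation points).
    obs_index : ndarray of int, shape (n,)
        For each observation i, the position j (0-based) with ``x[i] == t[j]``.
    is_observed : ndarray of bool, shape (m,)
        True at gridpoints that carry at least one observation.
    delta : ndarray, shape (m - 1,)
        Spacings ``t[k] - t[k-1]`` for k = 1..m-1 (all positive).
    """

    t: np.ndarray
    obs_index: np.ndarray
    is_observed: np.ndarray
    delta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", np.diff(self.t))

    @property
    def m(self) -> int:
        """Number of gridpoints."""
        return self.t.size

    @property
    def n_aug(self) -> int:
        """Number of augmentation-only gridpoints."""
        return int((~self.is_observed).sum())


def build_grid(x, x_aug=None) -> Grid:
    """Build the merged evaluation grid from observations and augmentation points.

    Parameters
    ----------
    x : array-like
        Observed predictor values (duplicates allowed).
    x_aug : array-like, optional
        Predictor values at which the latent function should additionally be
        evaluated.  Points equal to an observed value are absorbed (the
        gridpoint stays flagged observed); points outside the range of ``x``
        become extrapolation gridpoints.

    Returns
    -------
    Grid

    Notes
    -----
    Equality between an augmentation point and an observed value is exact
    floating-point equality; no tolerance-based merging is done, since silent
    merging would change the grid size unpredictably.  An augmentation point
    below ``min(x)`` becomes the new leftmost gridpoint, so the intercept of
    the process then refers to that point.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("predictor vector x is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor vector x contains non-finite values")
    if x_aug is None:
        x_aug = np.empty(0)
    x_aug = np.asarray(x_aug, dtype=float).ravel()
    if not np.all(np.isfinite(x_aug)):
        raise ValueError("augmentation points contain non-finite values")

    t_obs = np.unique(x)
    t = np.unique(np.concatenate([t_obs, x_aug]))
    is_observed = np.isin(t, t_obs)
    obs_index = np.searchsorted(t, x)
    return Grid(t=t, obs_index=obs_index, is_observed=is_observed)
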