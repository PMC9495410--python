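"""Thermodynamic promoter-occupancy activation function.

The production multiplier of gene i is a weighted average over promoter
binding states (subsets S of the n TFs):

    f_i = sum_S alpha_S w_S / sum_S w_S,
    w_S = r_S * prod_{j in S} v_j,     v_j = (y_j / k_ij) ** h_ij,

with r_S = 1 for subsets of size <= 1.  ``v_j`` is the binding intensity of
TF j at promoter i; alpha_S in [0, 1] is the expression level of binding
state S (0 = full repression, 1 = maximal production); r_S > 0 is the
synergy of a multi-TF state.  f is a convex combination of the alphas, so
it always lies in [min alpha, max alpha] ⊆ [0, 1].

Weights are combined in log space (equivalently, rescaled by the largest
subset weight) so that intensities as large as v ~ 1e5 per factor do not
overflow even for products over several TFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams, membership_matrix, subset_masks

__all__ = [
    "GeneRegulation",
    "intensity",
    "activation_single",
    "activation_pair",
    "activation_general",
    "activation_all",
    "activation_with_grads",
    "logic_surface",
]

_NEG = -1e18  # stand-in for log(0); keeps matmuls free of inf*0 NaNs
_TINY = 1e-300


def intensity(y, k, h):
    """Binding intensity v = (y/k)**h of a TF at abundance y."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("protein abundance must be nonnegative")
    return (y / k) ** h


def activation_single(alpha0: float, alpha1: float, v) -> float:
    """One-TF closed form f = (a0 + a1 v) / (1 + v)."""
    return (alpha0 + alpha1 * v) / (1.0 + v)


def activation_pair(alpha, r: float, v1, v2):
    """Two-TF closed form with synergy r on the doubly bound state."""
    a0, a1, a2, a3 = alpha
    num = a0 + a1 * v1 + a2 * v2 + a3 * r * v1 * v2
    den = 1.0 + v1 + v2 + r * v1 * v2
    return num / den


@dataclass
class GeneRegulation:
    """Regulatory input function of one gene.

    ``alpha`` has 2**n entries indexed by subset bitmask; ``r`` has
    2**n - n - 1 entries for subsets of size >= 2 in ascending-bitmask
    order.
    """

    k_row: np.ndarray
    h_row: np.ndarray
    alpha: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        self.k_row = np.atleast_1d(np.asarray(self.k_row, dtype=float))
        self.h_row = np.atleast_1d(np.asarray(self.h_row, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        n = self.k_row.size
        if self.alpha.size != 2**n:
            raise ValueError(f"alpha must have 2**n = {2**n} entries")

    @property
    def n(self) -> int:
        return self.k_row.size

    def r_full(self) -> np.ndarray:
        full = np.ones(2**self.n)
        full[subset_masks(self.n, min_size=2)] = self.r
        return full


def _log_intensity(y, k, h):
    """log v with v = (y/k)**h, robust at y = 0 (v=0 for h>0, v=1 for h=0)."""
    ly = np.log(np.maximum(y, _TINY))
    lv = h * (ly[..., None, :] - np.log(k)) if k.ndim == 2 else h * (ly - np.log(k))
    zero = (np.asarray(y) <= 0.0) & (h > 0)
    return np.where(zero, _NEG, lv)


def _state_posteriors(lv_row, alpha, r_full, member):
    """Normalized subset weights p_S and f from log intensities of one or
    more genes; lv_row shape (..., n), alpha/r_full (..., 2**n)."""
    with np.errstate(divide="ignore"):
        logw = np.log(r_full) + lv_row @ member.T
    logw = logw - logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    p = w / w.sum(axis=-1, keepdims=True)
    # anchor on alpha_0 so a constant alpha vector yields exactly that
    # constant regardless of rounding in sum(p) ~ 1
    a0 = alpha[..., :1]
    f = a0[..., 0] + ((alpha - a0) * p).sum(axis=-1)
    return p, f


def activation_general(reg: GeneRegulation, y) -> float:
    """n-TF activation f for one gene at protein abundances y."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y < 0):
        raise ValueError("protein abundance must be nonnegative")
    member = membership_matrix(reg.n)
    lv = _log_intensity(y, reg.k_row, reg.h_row)
    _, f = _state_posteriors(lv, reg.alpha, reg.r_full(), member)
    return float(f)


def activation_all(params: ModelParams, y, member: np.ndarray | None = None):
    """Activation vector f (length n) for every gene of a circuit."""
    if member is None:
        member = membership_matrix(params.n)
    lv = _log_intensity(np.asarray(y, dtype=float), params.k, params.h)
    _, f = _state_posteriors(lv, params.alpha, params.r_full(), member)
    return f


def activation_with_grads(k, h, alpha, r_full, y, member):
    """f and its partials for every gene; used by the adjoint simulator.

    Parameters are raw arrays: k, h (n, n); alpha, r_full (n, 2**n); y (n,).
    Returns ``f (n,)`` and gradients ``dfdy, dfdk, dfdh (n, n)``,
    ``dfdalpha, dfdr_full (n, 2**n)``; entry [i, j] differentiates gene i's
    activation with respect to TF j's quantity.
    """
    y = np.asarray(y, dtype=float)
    lv = _log_intensity(y, k, h)
    p, f = _state_posteriors(lv, alpha, r_full, member)
    resid = (alpha - f[:, None]) * p           # d f / d logw_S
    G = resid @ member                          # d f / d log v_ij
    with np.errstate(divide="ignore", invalid="ignore"):
        dfdy = np.where((y[None, :] > 0) & (h > 0), G * h / y[None, :], 0.0)
        dfdk = -G * h / k
        lyk = np.log(np.maximum(y, _TINY))[None, :] - np.log(k)
        dfdh = np.where((y[None, :] > 0), G * lyk, 0.0)
    return f, dfdy, dfdk, dfdh, p, resid / r_full


def logic_surface(
    params: ModelParams,
    output_gene: int,
    grids,
) -> pd.DataFrame:
    """Tabulate the activation of one gene over a grid of TF abundances.

    ``grids`` is a sequence of n 1-D abundance arrays (molecules/cell), one
    per TF.  Returns a long-format frame with columns ``y1..yn`` and ``f``,
    one row per grid point (meshgrid, 'ij' indexing).
    """
    n = params.n
    if not 0 <= output_gene < n:
        raise IndexError(f"output gene {output_gene} out of range for n={n}")
    if len(grids) != n:
        raise ValueError(f"need one abundance grid per TF ({n})")
    mesh = np.meshgrid(*[np.asarray(g, dtype=float) for g in grids], indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)  # (P, n)
    member = membership_matrix(n)
    lv = _log_intensity(pts, params.k[output_gene], params.h[output_gene])
    _, f = _state_posteriors(
        lv, params.alpha[output_gene], params.r_full()[output_gene], member
    )
    data = {f"y{j + 1}": pts[:, j] for j in range(n)}
    data["f"] = f
    return pd.DataFrame(data)
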