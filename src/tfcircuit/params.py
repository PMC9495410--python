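"""Parameter space for an n-TF genetic circuit.

A fully connected circuit of ``n`` transcription factors (TFs) is described
by per-gene kinetic rates, initial molecular abundances, a matrix of
TF-promoter binding constants and Hill coefficients, and thermodynamic
promoter-state weights:

* ``m``      maximum mRNA production rate (per second)
* ``delta``  mRNA decay rate (per second)
* ``s``      protein production rate per mRNA (per second)
* ``gamma``  protein decay rate (per second)
* ``x0/y0``  initial mRNA / protein molecules per cell
* ``k``      dissociation constants, ``k[i, j]`` = binding of TF j to the
             promoter of gene i (molecules per cell)
* ``h``      Hill coefficients, same shape as ``k`` (dimensionless)
* ``alpha``  expression weight of every promoter binding state (one weight
             per subset of the n TFs, 2**n per gene, in [0, 1])
* ``r``      synergy weight of every multi-TF binding state (subsets of
             size >= 2, ``2**n - n - 1`` per gene, in (0, 10))

Binding states are indexed by bitmask: subset ``S`` has mask
``sum(1 << j for j in S)``; masks run 0 .. 2**n - 1 in ascending order, and
the compact ``r`` array keeps only masks with popcount >= 2, ascending.

All parameters live in biologically bounded intervals.  For unconstrained
gradient optimization each scalar is stored on an unbounded real scale and
mapped into its interval ``(a, a + b)`` by a piecewise-sigmoid squash
followed by the affine map ``a + b * theta``.  The squash is the identity on
``[d, 1 - d]`` and logistic in the two boundary layers, so gradients inside
the working range are unit-scaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "ParameterBounds",
    "ModelParams",
    "SquashSpec",
    "VectorLayout",
    "count_parameters",
    "n_synergy",
    "subset_masks",
    "membership_matrix",
    "squash",
    "squash_grad",
    "unsquash",
    "decode",
    "encode",
    "init_params",
]

LAYOUT_VERSION = 1

#: ordered parameter families; this ordering defines the flat-vector layout
FAMILIES = ("m", "delta", "s", "gamma", "x0", "y0", "k", "h", "alpha", "r")


def count_parameters(n: int) -> int:
    """Total scalar degrees of freedom of an n-TF circuit.

    4n rates + 2n initial conditions + n**2 each for k and h + n*2**n
    alpha weights + n*(2**n - n - 1) synergy weights, which simplifies to
    ``n * (5 + n + 2**(n+1))``.
    """
    if n < 1:
        raise ValueError(f"network size must be >= 1, got {n}")
    return n * (5 + n + 2 ** (n + 1))


def n_synergy(n: int) -> int:
    """Number of synergy weights per gene (subsets of size >= 2)."""
    return 2**n - n - 1


def subset_masks(n: int, min_size: int = 0) -> np.ndarray:
    """Bitmasks of all TF subsets with popcount >= min_size, ascending."""
    masks = np.arange(2**n)
    if min_size > 0:
        pop = np.array([bin(m).count("1") for m in masks])
        masks = masks[pop >= min_size]
    return masks


def membership_matrix(n: int) -> np.ndarray:
    """(2**n, n) float matrix; entry [S, j] = 1 if TF j is in subset S."""
    masks = np.arange(2**n)
    return ((masks[:, None] >> np.arange(n)[None, :]) & 1).astype(float)


@dataclass(frozen=True)
class ParameterBounds:
    """Per-family (lower, upper) bounds; rates are per second, abundances
    molecules per cell."""

    m: Tuple[float, float] = (1e-4, 1e-2)
    delta: Tuple[float, float] = (1e-4, 1e-2)
    s: Tuple[float, float] = (1e-3, 1.0)
    gamma: Tuple[float, float] = (1e-3, 1.0)
    k: Tuple[float, float] = (1e2, 1e4)
    h: Tuple[float, float] = (0.0, 5.0)
    alpha: Tuple[float, float] = (0.0, 1.0)
    r: Tuple[float, float] = (0.0, 10.0)
    x0: Tuple[float, float] = (0.0, 1e2)
    y0: Tuple[float, float] = (0.0, 1e3)

    def __post_init__(self) -> None:
        for name in FAMILIES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} must satisfy lower < upper")

    def interval(self, name: str) -> Tuple[float, float]:
        return getattr(self, name)


@dataclass
class ModelParams:
    """Bounds-respecting parameter set for an n-TF circuit.

    ``alpha`` has shape (n, 2**n) indexed by subset bitmask; ``r`` has shape
    (n, 2**n - n - 1), holding synergy weights for subsets of size >= 2 in
    ascending-bitmask order (subsets of size <= 1 have implied r = 1).
    """

    n: int
    m: np.ndarray
    delta: np.ndarray
    s: np.ndarray
    gamma: np.ndarray
    x0: np.ndarray
    y0: np.ndarray
    k: np.ndarray
    h: np.ndarray
    alpha: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        n = self.n
        expected = {
            "m": (n,), "delta": (n,), "s": (n,), "gamma": (n,),
            "x0": (n,), "y0": (n,), "k": (n, n), "h": (n, n),
            "alpha": (n, 2**n), "r": (n, n_synergy(n)),
        }
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape} for n={n}"
                )
            setattr(self, name, arr)

    @property
    def n_params(self) -> int:
        return count_parameters(self.n)

    def r_full(self) -> np.ndarray:
        """Expand compact synergy weights to shape (n, 2**n) with r=1 for
        subsets of size <= 1."""
        full = np.ones((self.n, 2**self.n))
        full[:, subset_masks(self.n, min_size=2)] = self.r
        return full

    def validate(self, bounds: ParameterBounds) -> None:
        for name in FAMILIES:
            lo, hi = bounds.interval(name)
            arr = getattr(self, name)
            if np.any(arr < lo) or np.any(arr > hi):
                raise ValueError(f"parameter family {name!r} outside bounds ({lo}, {hi})")

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.n, *(getattr(self, f).copy() for f in FAMILIES)
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self, bounds: "ParameterBounds | None" = None) -> dict:
        """JSON-ready document: explicit field names, n, the bounds the set
        lives in (defaults assumed unless given) and a layout version tag."""
        if bounds is None:
            bounds = ParameterBounds()
        d = {
            "layout_version": LAYOUT_VERSION,
            "n": self.n,
            "bounds": {name: list(bounds.interval(name)) for name in FAMILIES},
        }
        for name in FAMILIES:
            d[name] = getattr(self, name).tolist()
        return d

    def to_json(self, path=None, bounds: "ParameterBounds | None" = None) -> str:
        text = json.dumps(self.to_dict(bounds), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        n = int(d["n"])
        return cls(n, *(np.asarray(d[name], dtype=float) for name in FAMILIES))

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- bounded <-> unbounded transform ---------------------------------------


@dataclass(frozen=True)
class SquashSpec:
    """Piecewise sigmoid squashing an unbounded real onto (0, 1).

    Identity on [d, 1-d]; logistic tails of width ~d chosen so the map is
    continuous at both break points.
    """

    d: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.d < 0.5:
            raise ValueError("boundary-layer width d must be in (0, 0.5)")

    @property
    def k1(self) -> float:
        return self.d * (1.0 + np.exp(-10.0 * self.d))

    @property
    def k2(self) -> float:
        return 10.0 * (1.0 - self.d) + np.log(self.d / (1.0 - self.d))


def squash(p, spec: SquashSpec = SquashSpec()):
    """Map unbounded p to theta in (0, 1); identity on [d, 1-d].

    The far tails underflow in double precision, so the output is clipped
    to the open unit interval's closest representable values.
    """
    p = np.asarray(p, dtype=float)
    d, k1, k2 = spec.d, spec.k1, spec.k2
    lower = k1 * expit(10.0 * p)
    upper = expit(10.0 * p - k2)
    out = np.where(p < d, lower, np.where(p > 1.0 - d, upper, p))
    out = np.clip(out, 5e-324, np.nextafter(1.0, 0.0))
    return out if out.ndim else float(out)


def squash_grad(p, spec: SquashSpec = SquashSpec()):
    """Derivative of :func:`squash` (piecewise; 1 on the identity region)."""
    p = np.asarray(p, dtype=float)
    d, k1, k2 = spec.d, spec.k1, spec.k2
    lo_sig = expit(10.0 * p)
    lower = 10.0 * k1 * lo_sig * (1.0 - lo_sig)
    up_sig = expit(10.0 * p - k2)
    upper = 10.0 * up_sig * (1.0 - up_sig)
    out = np.where(p < d, lower, np.where(p > 1.0 - d, upper, 1.0))
    return out if out.ndim else float(out)


def unsquash(theta, spec: SquashSpec = SquashSpec()):
    """Inverse of :func:`squash` on (0, 1)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0.0) or np.any(theta >= 1.0):
        raise ValueError("unsquash requires theta strictly inside (0, 1)")
    d, k1, k2 = spec.d, spec.k1, spec.k2
    with np.errstate(divide="ignore", invalid="ignore"):
        lower = 0.1 * np.log(theta / (k1 - theta))
        upper = 0.1 * (np.log(theta / (1.0 - theta)) + k2)
    out = np.where(theta < d, lower, np.where(theta > 1.0 - d, upper, theta))
    return out if out.ndim else float(out)


class VectorLayout:
    """Fixed flat ordering of ModelParams scalars.

    Families in order m, delta, s, gamma, x0, y0, k (row-major), h
    (row-major), alpha (gene-major then ascending bitmask), r (gene-major
    then ascending bitmask over subsets of size >= 2).
    """

    def __init__(self, n: int, bounds: ParameterBounds = ParameterBounds()):
        self.n = n
        self.bounds = bounds
        self.shapes = {
            "m": (n,), "delta": (n,), "s": (n,), "gamma": (n,),
            "x0": (n,), "y0": (n,), "k": (n, n), "h": (n, n),
            "alpha": (n, 2**n), "r": (n, n_synergy(n)),
        }
        self.slices: Dict[str, slice] = {}
        lo_parts, hi_parts = [], []
        offset = 0
        for name in FAMILIES:
            size = int(np.prod(self.shapes[name]))
            self.slices[name] = slice(offset, offset + size)
            lo, hi = bounds.interval(name)
            lo_parts.append(np.full(size, lo))
            hi_parts.append(np.full(size, hi))
            offset += size
        self.size = offset
        assert self.size == count_parameters(n)
        self.lo = np.concatenate(lo_parts)
        self.width = np.concatenate(hi_parts) - self.lo

    def flatten(self, params: ModelParams) -> np.ndarray:
        """Natural-scale flat vector in layout order."""
        return np.concatenate([getattr(params, f).ravel() for f in FAMILIES])

    def unflatten(self, vec: np.ndarray) -> ModelParams:
        if vec.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}, got {vec.shape}")
        fields = {
            name: vec[self.slices[name]].reshape(self.shapes[name])
            for name in FAMILIES
        }
        return ModelParams(self.n, **fields)


def decode(
    v: np.ndarray,
    bounds: ParameterBounds = ParameterBounds(),
    spec: SquashSpec = SquashSpec(),
    layout: VectorLayout | None = None,
) -> ModelParams:
    """Unbounded vector -> in-bounds ModelParams via squash then affine."""
    layout = layout or VectorLayout(n_from_size(len(v)), bounds)
    v = np.asarray(v, dtype=float)
    if v.shape != (layout.size,):
        raise ValueError(f"expected vector of length {layout.size}, got {v.shape}")
    theta = squash(v, spec)
    return layout.unflatten(layout.lo + layout.width * theta)


def encode(
    params: ModelParams,
    bounds: ParameterBounds = ParameterBounds(),
    spec: SquashSpec = SquashSpec(),
    margin: float = 1e-12,
) -> np.ndarray:
    """In-bounds ModelParams -> unbounded vector (inverse of decode).

    Values at an exact bound are nudged inward by ``margin`` (relative to
    the interval width) because the squash inverse diverges at 0 and 1.
    """
    params.validate(bounds)
    layout = VectorLayout(params.n, bounds)
    nat = layout.flatten(params)
    theta = (nat - layout.lo) / layout.width
    theta = np.clip(theta, margin, 1.0 - margin)
    return unsquash(theta, spec)


def n_from_size(size: int) -> int:
    """Invert count_parameters; raises if size matches no network size."""
    for n in range(1, 64):
        c = count_parameters(n)
        if c == size:
            return n
        if c > size:
            break
    raise ValueError(f"no network size has {size} parameters")


def init_params(
    n: int,
    rng: np.random.Generator,
    perturb_sd: float = 0.1,
    bounds: ParameterBounds = ParameterBounds(),
) -> ModelParams:
    """Draw a starting parameter set for optimization.

    Base values: m uniform on (1e-4, 1e-2); delta = 1.01e-4; s = 1.01e-1;
    gamma = 1.01e-3; k = 5e2; h = 2; alpha uniform on (0, 1); r = 1;
    x0 = 10 mRNA, y0 = 500 protein.  Decay rates start near their lower
    bounds so abundances do not collapse before optimization can act.  Every
    scalar is then multiplied by ``1 + z`` with ``z ~ Normal(0, perturb_sd)``
    and clipped just inside its bounds.
    """
    if not 0.0 <= perturb_sd < 1.0:
        raise ValueError("perturb_sd must be in [0, 1)")
    base = ModelParams(
        n=n,
        m=rng.uniform(1e-4, 1e-2, size=n),
        delta=np.full(n, 1.01e-4),
        s=np.full(n, 1.01e-1),
        gamma=np.full(n, 1.01e-3),
        x0=np.full(n, 10.0),
        y0=np.full(n, 500.0),
        k=np.full((n, n), 5e2),
        h=np.full((n, n), 2.0),
        alpha=rng.uniform(0.0, 1.0, size=(n, 2**n)),
        r=np.ones((n, n_synergy(n))),
    )
    layout = VectorLayout(n, bounds)
    nat = layout.flatten(base)
    if perturb_sd > 0.0:
        nat = nat * (1.0 + rng.normal(0.0, perturb_sd, size=nat.shape))
    eps = 1e-9 * layout.width
    nat = np.clip(nat, layout.lo + eps, layout.lo + layout.width - eps)
    return layout.unflatten(nat)
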