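"""Moment-based (arbitrary) polynomial chaos bases over identity space.

The heterogeneity distributions — natural frequency (continuous) and node
degree (discrete) — are known only through the sample carried by one network
realization.  For each marginal we build polynomials orthogonal under the
*empirical* measure of that sample, directly from its raw moments: the
degree-d monic polynomial sum_l c_l x^l satisfies the moment conditions

    sum_{l=0}^{d} c_l m_{l+k} = 0,   k = 0, .., d-1,   c_d = 1,

with m_j the j-th raw sample moment.  The linear system in c_0..c_{d-1} is
solved through an SVD pseudo-inverse of the (Hankel) moment matrix, followed
by a couple of extended-precision iterative-refinement sweeps: high-order
moment matrices are ill-conditioned and the refinement recovers empirical
orthogonality to near machine precision.

The 2-D basis is the tensor product of the two 1-D families, truncated by
total degree (a + b <= pmax, the default) or per coordinate, ordered
graded-lexicographically (ascending total degree, ties broken by ascending
frequency-degree).  The truncated basis has M = (1+pmax)(2+pmax)/2 members
under total-degree truncation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = [
    "ConditioningWarning",
    "HeterogeneitySample",
    "Poly1D",
    "Basis2D",
    "normalize",
    "raw_moments",
    "apc_1d",
    "tensor_basis",
    "design_matrix",
    "poly_distance",
    "save_basis",
    "load_basis",
]


class ConditioningWarning(UserWarning):
    """The moment matrix is numerically rank-deficient for this degree."""


def normalize(raw: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize with the population (divide-by-n) standard deviation.

    Returns (normalized values, center, scale).
    """
    raw = np.asarray(raw, dtype=float)
    if np.unique(raw).size < 2:
        raise ValueError("need >= 2 distinct values to normalize")
    center = raw.mean()
    scale = raw.std(ddof=0)
    if scale == 0.0:
        raise ValueError("zero standard deviation")
    return (raw - center) / scale, float(center), float(scale)


@dataclass
class HeterogeneitySample:
    """Paired (frequency, degree) sample with its normalization.

    The normalized coordinates have sample mean 0 and population sd 1 over
    the fitting node set.  By default the fitting node set is nodes
    1..N-1 — the nodes carrying independent co-moving coordinates — matching
    the normalization convention used for the surface fit; pass
    ``include_last=True`` to keep node N as an extra data point.
    """

    raw_omega: np.ndarray
    raw_kappa: np.ndarray
    omega: np.ndarray
    kappa: np.ndarray
    omega_center: float
    omega_scale: float
    kappa_center: float
    kappa_scale: float

    def __post_init__(self) -> None:
        n = len(self.raw_omega)
        for v in (self.raw_kappa, self.omega, self.kappa):
            if len(v) != n:
                raise ValueError("all sample vectors must share a length")

    @property
    def n(self) -> int:
        return len(self.omega)

    @classmethod
    def from_arrays(cls, raw_omega, raw_kappa) -> "HeterogeneitySample":
        raw_omega = np.asarray(raw_omega, dtype=float)
        raw_kappa = np.asarray(raw_kappa)
        om, oc, os_ = normalize(raw_omega)
        ka, kc, ks = normalize(raw_kappa.astype(float))
        return cls(raw_omega, raw_kappa, om, ka, oc, os_, kc, ks)

    @classmethod
    def from_ensemble(cls, ensemble, include_last: bool = False) -> "HeterogeneitySample":
        n = ensemble.N if include_last else ensemble.N - 1
        return cls.from_arrays(
            ensemble.omega_hat[:n], ensemble.network.degrees[:n]
        )

    def normalize_point(self, raw_omega, raw_kappa):
        """Map raw coordinates into this sample's normalized plane."""
        return (
            (np.asarray(raw_omega, float) - self.omega_center) / self.omega_scale,
            (np.asarray(raw_kappa, float) - self.kappa_center) / self.kappa_scale,
        )


@dataclass
class Poly1D:
    """One orthogonal polynomial: monomial coefficients, ascending powers.

    ``coeffs`` are scaled to unit empirical norm over the construction
    sample; ``empirical_norm`` is the norm of the monic representative, so
    ``coeffs * empirical_norm`` recovers the monic form.
    """

    degree: int
    coeffs: np.ndarray
    empirical_norm: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.degree + 1,):
            raise ValueError("coeffs length must be degree + 1")
        if self.coeffs[-1] == 0.0:
            raise ValueError("leading coefficient must be nonzero")
        if not (np.isfinite(self.empirical_norm) and self.empirical_norm > 0):
            raise ValueError("empirical_norm must be finite and positive")

    def __call__(self, x) -> np.ndarray:
        return npoly.polyval(np.asarray(x, dtype=float), self.coeffs)

    def monic_coeffs(self) -> np.ndarray:
        return self.coeffs * self.empirical_norm


def raw_moments(x: np.ndarray, max_order: int) -> np.ndarray:
    """Raw sample moments m_j = mean(x**j), j = 0..max_order.

    Each power is accumulated with compensated (exact) summation: high-order
    moments feed an ill-conditioned linear solve and deserve every digit.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    return np.array(
        [math.fsum(x**j) / n for j in range(max_order + 1)], dtype=float
    )


def apc_1d(sample: np.ndarray, max_degree: int) -> list[Poly1D]:
    """Orthogonal polynomials of degree 0..max_degree for an empirical measure.

    Mutually orthogonal under (1/n) sum_i p(x_i) q(x_i); each returned
    polynomial has unit empirical norm.  Warns when the moment matrix is
    numerically rank-deficient (degree too high for the sample).
    """
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    if n < 2 * max_degree + 1:
        raise ValueError(
            f"need >= {2 * max_degree + 1} sample points for degree {max_degree}"
        )
    m = raw_moments(sample, 2 * max_degree)
    polys: list[Poly1D] = []
    for d in range(max_degree + 1):
        if d == 0:
            monic = np.array([1.0])
        else:
            H = np.empty((d, d))
            for k in range(d):
                H[k, :] = m[k : k + d]
            rhs = -m[d : 2 * d]
            sv = np.linalg.svd(H, compute_uv=False)
            if sv[-1] <= sv[0] * np.finfo(float).eps * max(10.0, 10.0 * d):
                warnings.warn(
                    f"moment matrix nearly singular at degree {d} "
                    f"(sigma_min/sigma_max = {sv[-1] / sv[0]:.2e}); "
                    "polynomials beyond this degree are unreliable",
                    ConditioningWarning,
                    stacklevel=2,
                )
            Hinv = np.linalg.pinv(H)
            c = Hinv @ rhs
            # Iterative refinement with extended-precision residuals claws
            # back the digits the conditioning ate.
            Hl = H.astype(np.longdouble)
            rl = rhs.astype(np.longdouble)
            for _ in range(3):
                resid = rl - Hl @ c.astype(np.longdouble)
                c = c + Hinv @ resid.astype(float)
            monic = np.append(c, 1.0)
        vals = npoly.polyval(sample, monic)
        norm = math.sqrt(math.fsum(vals**2) / n)
        if norm == 0.0:
            raise ValueError(f"degenerate polynomial at degree {d}")
        polys.append(Poly1D(degree=d, coeffs=monic / norm, empirical_norm=norm))
    return polys


@dataclass
class Basis2D:
    """Tensor-product 2-D basis with a deterministic graded-lex ordering."""

    pmax: int
    index_set: tuple[tuple[int, int], ...]
    omega_polys: list[Poly1D]
    kappa_polys: list[Poly1D]
    truncation: str = "total"

    @property
    def M(self) -> int:
        return len(self.index_set)

    def evaluate(self, omega: np.ndarray, kappa: np.ndarray) -> np.ndarray:
        """Design-matrix block: entry (i, k) = psi^(k)(omega_i, kappa_i)."""
        omega = np.atleast_1d(np.asarray(omega, dtype=float))
        kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
        ovals = np.stack([p(omega) for p in self.omega_polys])
        kvals = np.stack([p(kappa) for p in self.kappa_polys])
        return np.stack(
            [ovals[a] * kvals[b] for a, b in self.index_set], axis=1
        )


def tensor_basis(
    omega_polys: list[Poly1D],
    kappa_polys: list[Poly1D],
    pmax: int,
    truncation: str = "total",
) -> Basis2D:
    """Assemble the truncated tensor-product basis.

    ``truncation="total"`` keeps pairs with a + b <= pmax (M = (1+pmax)
    (2+pmax)/2); ``"per_coordinate"`` keeps a <= pmax and b <= pmax.
    Ordering is graded lexicographic: ascending total degree, ties broken by
    ascending frequency-degree.
    """
    if len(omega_polys) < pmax + 1 or len(kappa_polys) < pmax + 1:
        raise ValueError("1-D families must contain degrees 0..pmax")
    if truncation == "total":
        idx = [
            (a, b)
            for a in range(pmax + 1)
            for b in range(pmax + 1)
            if a + b <= pmax
        ]
    elif truncation == "per_coordinate":
        idx = [(a, b) for a in range(pmax + 1) for b in range(pmax + 1)]
    else:
        raise ValueError(f"unknown truncation rule {truncation!r}")
    idx.sort(key=lambda ab: (ab[0] + ab[1], ab[0]))
    return Basis2D(
        pmax=pmax,
        index_set=tuple(idx),
        omega_polys=list(omega_polys[: pmax + 1]),
        kappa_polys=list(kappa_polys[: pmax + 1]),
        truncation=truncation,
    )


def design_matrix(basis: Basis2D, sample: HeterogeneitySample) -> np.ndarray:
    """n x M matrix of basis values at the sample's normalized points."""
    return basis.evaluate(sample.omega, sample.kappa)


def _coeff_tensor(basis: Basis2D) -> np.ndarray:
    """(M, 2, pmax+1) tensor of monic monomial coefficients, zero-padded."""
    width = basis.pmax + 1
    C = np.zeros((basis.M, 2, width))
    for k, (a, b) in enumerate(basis.index_set):
        ca = basis.omega_polys[a].monic_coeffs()
        cb = basis.kappa_polys[b].monic_coeffs()
        C[k, 0, : ca.size] = ca
        C[k, 1, : cb.size] = cb
    return C


def poly_distance(basisA: Basis2D, basisB: Basis2D) -> float:
    """2-norm distance between monomial-coefficient tensors, monic convention.

    Both bases are rescaled to monic 1-D factors first, so the (arbitrary)
    normalization convention cancels.
    """
    if basisA.pmax != basisB.pmax or basisA.index_set != basisB.index_set:
        raise ValueError("bases must share pmax and ordering")
    return float(np.linalg.norm(_coeff_tensor(basisA) - _coeff_tensor(basisB)))


# ---------------------------------------------------------------------------
# serialization


def save_basis(path, basis: Basis2D, sample: HeterogeneitySample | None = None) -> None:
    """JSON document: pmax, ordering tag, coefficients, norms, (center, scale)."""
    doc = {
        "pmax": basis.pmax,
        "truncation": basis.truncation,
        "ordering": "graded-lex-omega",
        "index_set": [list(ab) for ab in basis.index_set],
        "omega_polys": [
            {"degree": p.degree, "coeffs": p.coeffs.tolist(), "empirical_norm": p.empirical_norm}
            for p in basis.omega_polys
        ],
        "kappa_polys": [
            {"degree": p.degree, "coeffs": p.coeffs.tolist(), "empirical_norm": p.empirical_norm}
            for p in basis.kappa_polys
        ],
    }
    if sample is not None:
        doc["normalization"] = {
            "omega": [sample.omega_center, sample.omega_scale],
            "kappa": [sample.kappa_center, sample.kappa_scale],
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_basis(path) -> tuple[Basis2D, dict]:
    with open(path) as fh:
        doc = json.load(fh)

    def _polys(key):
        return [
            Poly1D(d["degree"], np.array(d["coeffs"]), d["empirical_norm"])
            for d in doc[key]
        ]

    basis = Basis2D(
        pmax=doc["pmax"],
        index_set=tuple(tuple(ab) for ab in doc["index_set"]),
        omega_polys=_polys("omega_polys"),
        kappa_polys=_polys("kappa_polys"),
        truncation=doc["truncation"],
    )
    return basis, doc.get("normalization", {})
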