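"""Scalar descriptors of a plant-pollinator interaction matrix.

Implemented descriptors
-----------------------
C
    Connectance, the realised fraction of possible links: ``C = I / (P * A)``.
H'
    Shannon diversity of interactions (natural log) over the relative
    interaction frequencies of all realised links.
LD
    Quantitative linkage density: the weighted mean effective number of
    partners per species, using the exponential of the per-species Shannon
    entropy of its interaction distribution.
T, N
    Binary matrix temperature in [0, 100] (Atmar-Patterson style packed
    matrix with a fill-dependent isocline) and the nestedness score
    ``N = 1 - T/100`` so that 1 means perfectly nested.
wNODF
    Weighted NODF nestedness in [0, 100]: paired overlap and decreasing
    fill over rows and columns, counting strict frequency decreases between
    every pair with strictly decreasing marginal totals.
ISA
    Interaction strength asymmetry in [-1, 1]: the mean, over links, of the
    difference between the pollinator's dependence on the plant and the
    plant's dependence on the pollinator, normalised by the larger of the
    two.  Positive values mean pollinators depend more on plants than vice
    versa.

All entropies are reported in nats; the exponential-entropy quantities
(effective partner numbers) are base-invariant.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .network_build import InteractionMatrix

__all__ = [
    "NetworkMetrics",
    "connectance",
    "connectance_from_counts",
    "shannon_diversity",
    "linkage_density",
    "temperature_nestedness",
    "wnodf",
    "strength_asymmetry",
    "compute_metrics",
    "METRICS",
]


@dataclasses.dataclass
class NetworkMetrics:
    """One value per descriptor for one interaction matrix."""

    C: float
    Hprime: float
    LD: float
    T: float
    N: float
    wNODF: float
    ISA: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _W(m) -> np.ndarray:
    W = m.W if isinstance(m, InteractionMatrix) else np.asarray(m, dtype=float)
    if W.ndim != 2 or W.size == 0:
        raise ValueError("interaction matrix must be a non-empty 2-D array")
    if (W < 0).any():
        raise ValueError("interaction weights must be non-negative")
    return np.asarray(W, dtype=float)


def _B(m) -> np.ndarray:
    if isinstance(m, InteractionMatrix):
        return np.asarray(m.B, dtype=np.int8)
    return (_W(m) > 0).astype(np.int8)


# ----------------------------------------------------------------------
def connectance(m) -> float:
    """Fraction of realised links: I / (P * A)."""
    B = _B(m)
    P, A = B.shape
    if P < 1 or A < 1:
        raise ValueError("matrix must have at least one plant and one pollinator")
    return float(B.sum()) / (P * A)


def connectance_from_counts(I: int, P: int, A: int) -> float:
    """Connectance from the summary counts alone (I links, P plants, A pollinators)."""
    if P < 1 or A < 1:
        raise ValueError("P and A must be positive")
    if not 0 <= I <= P * A:
        raise ValueError("I must lie in [0, P*A]")
    return I / (P * A)


# ----------------------------------------------------------------------
def shannon_diversity(m) -> float:
    """Shannon diversity H' (nats) of the relative interaction frequencies."""
    W = _W(m)
    tot = W.sum()
    if tot <= 0:
        raise ValueError("all-zero matrix: H' undefined")
    p = W[W > 0] / tot
    return float(-(p * np.log(p)).sum())


def _entropy(v: np.ndarray) -> float:
    """Shannon entropy (nats) of a non-negative weight vector."""
    s = v.sum()
    if s <= 0:
        return 0.0
    p = v[v > 0] / s
    return float(-(p * np.log(p)).sum())


def linkage_density(m) -> float:
    """Quantitative linkage density (effective links per species).

    LD = 1/2 [ sum_j (w_.j / w_..) exp(H of column j over plants)
             + sum_i (w_i. / w_..) exp(H of row i over pollinators) ].
    """
    W = _W(m)
    tot = W.sum()
    if tot <= 0:
        raise ValueError("all-zero matrix: LD undefined")
    col = 0.0
    for j in range(W.shape[1]):
        wj = W[:, j].sum()
        if wj > 0:
            col += (wj / tot) * np.exp(_entropy(W[:, j]))
    row = 0.0
    for i in range(W.shape[0]):
        wi = W[i, :].sum()
        if wi > 0:
            row += (wi / tot) * np.exp(_entropy(W[i, :]))
    return 0.5 * (col + row)


# ----------------------------------------------------------------------
# Matrix temperature / nestedness
# ----------------------------------------------------------------------

def _isocline_exponent(fill: float) -> float:
    """Exponent p of the isocline x**p + y**p = 1 whose area equals *fill*.

    The area under the curve is Gamma(1 + 1/p)^2 / Gamma(1 + 2/p), which
    increases monotonically from 0 (p -> 0) to 1 (p -> inf); p = 1 gives the
    triangular half-filled matrix.
    """
    fill = min(max(fill, 1e-6), 1 - 1e-6)

    def area(logp):
        p = np.exp(logp)
        return np.exp(2 * gammaln(1 + 1 / p) - gammaln(1 + 2 / p)) - fill

    logp = brentq(area, np.log(1e-3), np.log(1e3), xtol=1e-12)
    return float(np.exp(logp))


def _pack(B: np.ndarray) -> np.ndarray:
    """Sort rows and columns by marginal totals (descending).

    Ties are broken by cross-marginal weighted sums so the packing — and
    hence the temperature — is invariant to the input row/column order.
    """
    rt = B.sum(axis=1).astype(float)
    ct = B.sum(axis=0).astype(float)
    rkey = rt + 1e-9 * (B @ ct) / max(ct.sum(), 1.0)
    ckey = ct + 1e-9 * (rt @ B) / max(rt.sum(), 1.0)
    ro = np.argsort(-rkey, kind="stable")
    co = np.argsort(-ckey, kind="stable")
    return B[np.ix_(ro, co)]

#: Atmar-Patterson normalisation: maximum expected unexpectedness.
_U_MAX = 0.04145


def temperature_nestedness(m) -> tuple[float, float]:
    """Matrix temperature T in [0, 100] and nestedness N = 1 - T/100.

    The binary matrix is packed by marginal totals, an isocline of perfect
    nestedness is drawn for the observed fill, and every presence beyond
    the isocline or absence before it contributes its squared normalised
    distance (measured along the cell's diagonal) to the temperature.
    Degenerate single-row or single-column matrices are perfectly packable,
    so T is 0 by convention.
    """
    B = _B(m)
    if B.sum() < 1:
        raise ValueError("temperature undefined for a matrix with no links")
    P, A = B.shape
    if P == 1 or A == 1:
        return 0.0, 1.0
    Bp = _pack(B)
    fill = Bp.sum() / (P * A)
    p = _isocline_exponent(fill)

    # normalised cell centres; (0, 0) is the packed (generalist) corner
    y = (np.arange(P) + 0.5) / P
    x = (np.arange(A) + 0.5) / A
    X, Y = np.meshgrid(x, y)

    inside = X**p + Y**p < 1.0  # expected presence
    unexpected = (Bp == 1) & ~inside | (Bp == 0) & inside

    u = np.zeros_like(X)
    ui, uj = np.nonzero(unexpected)
    for i, j in zip(ui, uj):
        cx, cy = X[i, j], Y[i, j]
        # crossing of the diagonal (cx + t, cy + t) with the isocline
        f = lambda t: (cx + t) ** p + (cy + t) ** p - 1.0
        lo, hi = -min(cx, cy), min(1 - cx, 1 - cy)
        try:
            t = brentq(f, lo, hi, xtol=1e-12)
        except ValueError:
            t = lo if abs(f(lo)) < abs(f(hi)) else hi
        d = abs(t)
        D = hi - lo
        u[i, j] = (d / D) ** 2 if D > 0 else 0.0

    T = 100.0 * u.mean() / _U_MAX
    T = float(min(max(T, 0.0), 100.0))
    return T, 1.0 - T / 100.0


# ----------------------------------------------------------------------
# Weighted NODF
# ----------------------------------------------------------------------

def _wnodf_axis(M: np.ndarray) -> tuple[float, int]:
    """Sum of pair terms over the rows of M, plus the number of row pairs.

    For an unordered row pair the row with the strictly larger marginal
    total is the reference; the term is the percentage of the other row's
    filled cells whose weight is strictly smaller than the reference's in
    the same column.  Equal totals (or an empty lesser row) score 0.
    """
    n = M.shape[0]
    if n < 2:
        return 0.0, 0
    tot = M.sum(axis=1)
    pos = M > 0
    # less[u, v, c]: 0 < M[v, c] < M[u, c]
    less = (M[None, :, :] < M[:, None, :]) & pos[None, :, :]
    numer = less.sum(axis=2).astype(float)
    denom = pos.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom[None, :] > 0, numer / np.maximum(denom[None, :], 1), 0.0)
    valid = tot[:, None] > tot[None, :]
    return float((100.0 * frac * valid).sum()), n * (n - 1) // 2


def wnodf(m) -> float:
    """Weighted NODF in [0, 100] over all row pairs and column pairs."""
    W = _W(m)
    if W.sum() <= 0:
        raise ValueError("all-zero matrix: wNODF undefined")
    srow, nrow = _wnodf_axis(W)
    scol, ncol = _wnodf_axis(W.T)
    npairs = nrow + ncol
    if npairs == 0:
        raise ValueError("wNODF needs at least two rows or two columns")
    return (srow + scol) / npairs


# ----------------------------------------------------------------------
def strength_asymmetry(m) -> float:
    """Mean normalised dependence asymmetry over links, in [-1, 1].

    For link (i, j): the pollinator's dependence d_A = W_ij / column j
    total, the plant's dependence d_P = W_ij / row i total; the link's
    asymmetry is (d_A - d_P) / max(d_A, d_P).  Positive values indicate
    greater dependence in the pollinator guild.
    """
    W = _W(m)
    if W.sum() <= 0:
        raise ValueError("all-zero matrix: ISA undefined")
    rows = W.sum(axis=1, keepdims=True)
    cols = W.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        dA = np.where(cols > 0, W / np.where(cols > 0, cols, 1), 0.0)
        dP = np.where(rows > 0, W / np.where(rows > 0, rows, 1), 0.0)
    link = W > 0
    asym = (dA - dP) / np.maximum(dA, dP, where=link, out=np.ones_like(W))
    return float(asym[link].mean())


# ----------------------------------------------------------------------
def compute_metrics(m) -> NetworkMetrics:
    """All descriptors of one matrix."""
    T, N = temperature_nestedness(m)
    return NetworkMetrics(
        C=connectance(m),
        Hprime=shannon_diversity(m),
        LD=linkage_density(m),
        T=T,
        N=N,
        wNODF=wnodf(m),
        ISA=strength_asymmetry(m),
    )


#: Named metric functions, as used by the contrast battery.
METRICS = {
    "C": connectance,
    "Hprime": shannon_diversity,
    "LD": linkage_density,
    "N": lambda m: temperature_nestedness(m)[1],
    "wNODF": wnodf,
    "ISA": strength_asymmetry,
}
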