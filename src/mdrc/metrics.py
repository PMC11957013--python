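"""Scalar summaries of voxel distributions: moments, bins, Δω/2π rates, FA/DEC.

A voxel's component distribution is reduced to weight-normalized statistics
E[x], V[x], C[x,y] of x, y ∈ {Diso, DΔ², R1, R2} evaluated at a probe
frequency ω, to signal fractions of three (Diso, DΔ²) bins separating
anisotropic-slow (white-matter-like), isotropic-slow (gray-matter-like) and
fast (free-fluid-like) pools, to per-Hz frequency-dependence rates
Δω/2π[·] between two probe frequencies, and to fractional-anisotropy /
principal-direction summaries of the mean diffusion tensor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .forward import DiffusionComponent, VoxelDistribution
from .inversion import VoxelEnsemble

__all__ = [
    "QUANTITIES",
    "BinDefinition",
    "Moments",
    "component_values",
    "weighted_moments",
    "assign_bin",
    "assign_bins",
    "bin_fractions",
    "bin_resolved_mean",
    "delta_omega_metric",
    "mean_tensor",
    "fractional_anisotropy",
    "fa_of_mean_tensor",
    "dec_map",
    "summarize_voxel",
    "summarize_voxels",
]

QUANTITIES = ("diso", "ddelta2", "r1", "r2")


@dataclass(frozen=True)
class BinDefinition:
    """Thresholds partitioning the (Diso, DΔ²) plane into three pools.

    bin 1: DΔ² > 0.25 and Diso < 1e-9 m²/s (anisotropic, slow; WM-like)
    bin 2: DΔ² < 0.25 and Diso < 1e-9 m²/s (isotropic, slow; GM-like)
    bin 3: Diso > 1e-9 m²/s (fast; CSF/fluid-like)

    The Diso test is applied first so bin 3 captures all fast components
    regardless of anisotropy; boundary values fall to the later branch,
    making the bins a true partition.
    """

    diso_threshold: float = 1e-9
    ddelta2_threshold: float = 0.25


def component_values(
    dist: VoxelDistribution, quantity: str, omega: float
) -> np.ndarray:
    """Per-component values of a named quantity at probe frequency ω (rad/s)."""
    if quantity in ("r1", "r2"):
        return getattr(dist, quantity)
    d_iso, d_delta = dist.iso_anisotropy(float(omega))
    if quantity == "diso":
        return d_iso
    if quantity == "ddelta2":
        return d_delta**2
    raise ValueError(f"unknown quantity {quantity!r}; expected one of {QUANTITIES}")


@dataclass(frozen=True)
class Moments:
    """Weight-normalized first/second moments of a quantity pair."""

    e_x: float
    e_y: float
    v_x: float
    v_y: float
    c_xy: float


def weighted_moments(
    distribution: VoxelDistribution,
    quantity_pair: tuple[str, str] | str,
    omega: float,
) -> Moments:
    """E, V of each quantity and their covariance C at probe frequency ω.

    Moments are weighted by component weights (population convention, no
    small-sample correction: the weights are signal fractions, not counts).
    """
    if isinstance(quantity_pair, str):
        quantity_pair = (quantity_pair, quantity_pair)
    w = distribution.w
    total = w.sum()
    if total <= 0:
        raise ValueError("moments undefined for zero total weight")
    x = component_values(distribution, quantity_pair[0], omega)
    y = component_values(distribution, quantity_pair[1], omega)
    p = w / total
    e_x, e_y = float(p @ x), float(p @ y)
    v_x = float(p @ (x - e_x) ** 2)
    v_y = float(p @ (y - e_y) ** 2)
    c_xy = float(p @ ((x - e_x) * (y - e_y)))
    return Moments(e_x=e_x, e_y=e_y, v_x=v_x, v_y=v_y, c_xy=c_xy)


def assign_bins(
    dist: VoxelDistribution,
    omega_bin: float,
    bins: BinDefinition = BinDefinition(),
) -> np.ndarray:
    """Bin id (1, 2 or 3) of every component, evaluated at ω = omega_bin."""
    d_iso, d_delta = dist.iso_anisotropy(float(omega_bin))
    dd2 = d_delta**2
    out = np.full(len(dist), 2, dtype=int)
    out[dd2 > bins.ddelta2_threshold] = 1
    out[d_iso > bins.diso_threshold] = 3
    return out


def assign_bin(
    component: DiffusionComponent,
    omega_bin: float,
    bins: BinDefinition = BinDefinition(),
) -> int:
    """Bin id of one component (see :class:`BinDefinition`)."""
    dist = VoxelDistribution.from_components([component])
    return int(assign_bins(dist, omega_bin, bins)[0])


def bin_fractions(
    dist: VoxelDistribution,
    omega_bin: float,
    bins: BinDefinition = BinDefinition(),
) -> np.ndarray:
    """Signal-weight fractions (f_bin1, f_bin2, f_bin3); they sum to 1."""
    total = dist.w.sum()
    if total <= 0:
        raise ValueError("bin fractions undefined for zero total weight")
    ids = assign_bins(dist, omega_bin, bins)
    return np.array([dist.w[ids == b].sum() for b in (1, 2, 3)]) / total


def bin_resolved_mean(
    dist: VoxelDistribution,
    quantity: str,
    omega: float,
    omega_bin: float | None = None,
    bins: BinDefinition = BinDefinition(),
) -> np.ndarray:
    """Per-bin weighted means E[x | bin]; NaN for empty bins.

    ``omega_bin`` (bin assignment frequency) defaults to the evaluation ω.
    """
    if omega_bin is None:
        omega_bin = omega
    ids = assign_bins(dist, omega_bin, bins)
    x = component_values(dist, quantity, omega)
    out = np.full(3, np.nan)
    for b in (1, 2, 3):
        sel = ids == b
        wsum = dist.w[sel].sum()
        if wsum > 0:
            out[b - 1] = float(dist.w[sel] @ x[sel] / wsum)
    return out


def delta_omega_metric(
    distribution: VoxelDistribution,
    quantity: tuple[str, str] | str,
    omega_min: float,
    omega_max: float,
    stat: str = "E",
) -> float:
    """Per-Hz frequency-dependence rate of a distribution statistic.

    Δω/2π[stat] = (stat(ωmax) - stat(ωmin)) / ((ωmax - ωmin)/2π), with stat
    one of 'E', 'V' (of a single quantity) or 'C' (of a quantity pair).
    Frequencies are angular (rad/s); the result is per Hz.
    """
    if omega_max <= omega_min:
        raise ValueError("omega_max must exceed omega_min")
    if stat not in ("E", "V", "C"):
        raise ValueError(f"stat must be 'E', 'V' or 'C', got {stat!r}")
    m_lo = weighted_moments(distribution, quantity, omega_min)
    m_hi = weighted_moments(distribution, quantity, omega_max)
    attr = {"E": "e_x", "V": "v_x", "C": "c_xy"}[stat]
    return (getattr(m_hi, attr) - getattr(m_lo, attr)) / (
        (omega_max - omega_min) / (2.0 * np.pi)
    )


def mean_tensor(distribution: VoxelDistribution, omega: float) -> np.ndarray:
    """Weight-averaged lab-frame diffusion tensor D̄(ω)."""
    total = distribution.w.sum()
    if total <= 0:
        raise ValueError("mean tensor undefined for zero total weight")
    return np.einsum("i,iab->ab", distribution.w / total,
                     distribution.lab_tensors(omega))


def fractional_anisotropy(tensor: np.ndarray) -> float:
    """Standard FA of a symmetric 3x3 tensor, in [0, 1]."""
    lam = np.linalg.eigvalsh(tensor)
    norm = np.sqrt((lam**2).sum())
    if norm == 0:
        raise ValueError("FA undefined for the zero tensor")
    mean = lam.mean()
    return float(np.sqrt(1.5 * ((lam - mean) ** 2).sum()) / norm)


def fa_of_mean_tensor(distribution: VoxelDistribution, omega: float) -> float:
    """FA of the voxel's weight-averaged diffusion tensor at ω."""
    return fractional_anisotropy(mean_tensor(distribution, omega))


@dataclass(frozen=True)
class DECResult:
    """Median-FA direction-encoded color summary of a bootstrap ensemble."""

    fa: float
    eigenvector: np.ndarray
    rgb: np.ndarray


def dec_map(ensemble: VoxelEnsemble, omega: float) -> DECResult:
    """Median FA / median eigenvector over bootstrap solutions.

    Per solution, FA and principal eigenvector are those of its mean tensor
    D̄(ω).  The median FA is the sample median; the median eigenvector is the
    eigenvector of the solution whose FA is closest to that median.  RGB is
    the absolute eigenvector scaled by FA (antipodally symmetric).
    """
    fas, vecs = [], []
    for sol in ensemble.solutions:
        if len(sol) == 0 or sol.w.sum() <= 0:
            continue
        tensor = mean_tensor(sol, omega)
        lam, v = np.linalg.eigh(tensor)
        fas.append(fractional_anisotropy(tensor))
        vecs.append(v[:, -1])
    if not fas:
        raise ValueError("ensemble has no weighted solutions")
    fas = np.asarray(fas)
    med = float(np.median(fas))
    pick = int(np.argmin(np.abs(fas - med)))
    vec = vecs[pick]
    return DECResult(fa=float(fas[pick]), eigenvector=vec, rgb=np.abs(vec) * fas[pick])


def summarize_voxel(
    distribution: VoxelDistribution,
    omega_ref: float,
    omega_band: tuple[float, float],
    omega_bin: float | None = None,
    bins: BinDefinition = BinDefinition(),
) -> dict[str, float]:
    """All scalar maps of one voxel distribution.

    Parameters
    ----------
    omega_ref : float
        Probe frequency (rad/s) for the non-Δω statistics (defaults used by
        callers: ωmin of the protocol's b-weighted frequency band).
    omega_band : (float, float)
        (ωmin, ωmax) in rad/s for the Δω/2π metrics.
    omega_bin : float, optional
        Frequency at which bin membership is evaluated; defaults to ωmin.

    Returns
    -------
    dict
        Keys: total signal ``s0``; ``E_*``, ``V_*`` for the four quantities;
        covariances ``C_diso_ddelta2``, ``C_diso_r1``, ``C_diso_r2``,
        ``C_ddelta2_r1``, ``C_ddelta2_r2``, ``C_r1_r2``; bin fractions
        ``f_bin1..3``; bin-resolved means ``E_<q>_bin<b>``; Δω rates
        ``dw_E_diso``, ``dw_E_ddelta2``, ``dw_V_diso``, ``dw_V_ddelta2``,
        ``dw_C_diso_ddelta2`` and bin-resolved ``dw_E_diso_bin<b>`` /
        ``dw_E_ddelta2_bin<b>``; ``fa``.
    """
    omega_min, omega_max = omega_band
    if omega_bin is None:
        omega_bin = omega_min
    out: dict[str, float] = {"s0": distribution.total_weight}
    if len(distribution) == 0 or distribution.total_weight <= 0:
        return out

    for q in QUANTITIES:
        m = weighted_moments(distribution, q, omega_ref)
        out[f"E_{q}"] = m.e_x
        out[f"V_{q}"] = m.v_x
    for qx, qy in (("diso", "ddelta2"), ("diso", "r1"), ("diso", "r2"),
                   ("ddelta2", "r1"), ("ddelta2", "r2"), ("r1", "r2")):
        out[f"C_{qx}_{qy}"] = weighted_moments(distribution, (qx, qy), omega_ref).c_xy

    f = bin_fractions(distribution, omega_bin, bins)
    for b in (1, 2, 3):
        out[f"f_bin{b}"] = float(f[b - 1])
    for q in QUANTITIES:
        per_bin = bin_resolved_mean(distribution, q, omega_ref, omega_bin, bins)
        for b in (1, 2, 3):
            out[f"E_{q}_bin{b}"] = float(per_bin[b - 1])

    out["dw_E_diso"] = delta_omega_metric(distribution, "diso", omega_min, omega_max, "E")
    out["dw_E_ddelta2"] = delta_omega_metric(distribution, "ddelta2", omega_min, omega_max, "E")
    out["dw_V_diso"] = delta_omega_metric(distribution, "diso", omega_min, omega_max, "V")
    out["dw_V_ddelta2"] = delta_omega_metric(distribution, "ddelta2", omega_min, omega_max, "V")
    out["dw_C_diso_ddelta2"] = delta_omega_metric(
        distribution, ("diso", "ddelta2"), omega_min, omega_max, "C")
    # bin-resolved Δω rates of the per-bin means (fixed membership at ω_bin)
    hz = (omega_max - omega_min) / (2.0 * np.pi)
    for q in ("diso", "ddelta2"):
        lo = bin_resolved_mean(distribution, q, omega_min, omega_bin, bins)
        hi = bin_resolved_mean(distribution, q, omega_max, omega_bin, bins)
        for b in (1, 2, 3):
            out[f"dw_E_{q}_bin{b}"] = float((hi[b - 1] - lo[b - 1]) / hz)

    out["fa"] = fa_of_mean_tensor(distribution, omega_ref)
    return out


def summarize_voxels(
    distributions: Iterable[VoxelDistribution],
    omega_ref: float,
    omega_band: tuple[float, float],
    omega_bin: float | None = None,
    bins: BinDefinition = BinDefinition(),
) -> pd.DataFrame:
    """Per-voxel summary maps as a DataFrame (one row per voxel)."""
    rows = [
        summarize_voxel(d, omega_ref, omega_band, omega_bin, bins)
        for d in distributions
    ]
    return pd.DataFrame(rows)
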