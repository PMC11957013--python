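"""Multi-component frequency-dependent diffusion-relaxation signal model.

Each voxel is a sum of mono-exponential components.  Component ``i`` carries
an axisymmetric frequency-dependent diffusion tensor D_i(ω) (Lorentzian
dispersion from the long-time diffusivities D∥, D⊥ up to the restriction-free
isotropic value D0, with transition frequencies Γ∥, Γ⊥), longitudinal and
transverse relaxation rates R1, R2, and a nonnegative weight w:

    S(b(ω), τR, τE) = Σ_i w_i · exp(-∫ b(ω):D_i(ω) dω)
                           · (1 - exp(-τR·R1_i)) · exp(-τE·R2_i)

with saturation-recovery longitudinal weighting (τR is the time from
saturation to excitation) and spin-echo transverse weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .encoding import AcquisitionPoint, EncodingSpectrum, Protocol

__all__ = [
    "DiffusionComponent",
    "VoxelDistribution",
    "axial_diffusivity",
    "radial_diffusivity",
    "lab_frame_tensor",
    "iso_and_anisotropy",
    "signal",
    "signal_matrix",
    "InconsistentEncodingError",
]

PARAM_NAMES = (
    "d0", "d_par", "d_perp", "gamma_par", "gamma_perp",
    "theta", "phi", "r1", "r2", "w",
)


class InconsistentEncodingError(ValueError):
    """Spectrum's integrated b does not match the acquisition point's b."""


@dataclass(frozen=True)
class DiffusionComponent:
    """One mono-exponential D(ω)-R1-R2 component.

    Parameters
    ----------
    d0 : float
        High-frequency (restriction-free) isotropic diffusivity, m^2/s.
    d_par, d_perp : float
        Zero-frequency axial/radial diffusivities, m^2/s; both <= d0.
    gamma_par, gamma_perp : float
        Axial/radial Lorentzian transition frequencies, rad/s (angular).
    theta, phi : float
        Principal-axis polar/azimuthal angles, rad.
    r1, r2 : float
        Longitudinal/transverse relaxation rates, 1/s.
    w : float
        Nonnegative signal weight.
    """

    d0: float
    d_par: float
    d_perp: float
    gamma_par: float
    gamma_perp: float
    theta: float = 0.0
    phi: float = 0.0
    r1: float = 1.0
    r2: float = 20.0
    w: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.d_par <= self.d0):
            raise ValueError(
                f"need 0 < d_par <= d0, got d_par={self.d_par}, d0={self.d0}"
            )
        if not (0.0 < self.d_perp <= self.d0):
            raise ValueError(
                f"need 0 < d_perp <= d0, got d_perp={self.d_perp}, d0={self.d0}"
            )
        if self.gamma_par <= 0 or self.gamma_perp <= 0:
            raise ValueError("transition frequencies must be > 0")
        if self.w < 0:
            raise ValueError(f"weight must be >= 0, got {self.w}")

    @property
    def principal_axis(self) -> np.ndarray:
        return np.array([
            np.sin(self.theta) * np.cos(self.phi),
            np.sin(self.theta) * np.sin(self.phi),
            np.cos(self.theta),
        ])

    def with_weight(self, w: float) -> "DiffusionComponent":
        return replace(self, w=w)


def _lorentzian(d0, d_low, gamma, omega):
    # D(ω) = D0 - (D0 - D_low) / (1 + ω²/Γ²): rises from D_low at ω=0 to D0
    return d0 - (d0 - d_low) / (1.0 + (omega / gamma) ** 2)


def axial_diffusivity(comp: DiffusionComponent, omega) -> np.ndarray | float:
    """Axial diffusivity D∥(ω), m^2/s.  Even and nondecreasing in |ω|."""
    return _lorentzian(comp.d0, comp.d_par, comp.gamma_par, np.asarray(omega, float))


def radial_diffusivity(comp: DiffusionComponent, omega) -> np.ndarray | float:
    """Radial diffusivity D⊥(ω), m^2/s."""
    return _lorentzian(comp.d0, comp.d_perp, comp.gamma_perp, np.asarray(omega, float))


def lab_frame_tensor(comp: DiffusionComponent, omega: float) -> np.ndarray:
    """Lab-frame diffusion tensor at ω: D⊥(ω)·I + (D∥(ω)-D⊥(ω))·uu^T."""
    d_par = axial_diffusivity(comp, omega)
    d_perp = radial_diffusivity(comp, omega)
    u = comp.principal_axis
    return d_perp * np.eye(3) + (d_par - d_perp) * np.outer(u, u)


def iso_and_anisotropy(comp: DiffusionComponent, omega) -> tuple:
    """Isotropic diffusivity Diso(ω) and normalized anisotropy DΔ(ω).

    Diso = (D∥ + 2 D⊥)/3 ; DΔ = (D∥ - D⊥)/(3 Diso), in [-0.5, 1].
    """
    d_par = axial_diffusivity(comp, omega)
    d_perp = radial_diffusivity(comp, omega)
    d_iso = (d_par + 2.0 * d_perp) / 3.0
    if np.any(np.asarray(d_iso) <= 0):
        raise ValueError("anisotropy undefined for zero isotropic diffusivity")
    return d_iso, (d_par - d_perp) / (3.0 * d_iso)


class VoxelDistribution:
    """Discrete distribution of diffusion-relaxation components in one voxel.

    Stores components as parallel arrays (struct-of-arrays) for fast
    vectorized evaluation; iterate to obtain :class:`DiffusionComponent`
    views.
    """

    def __init__(self, **params):
        arrays = {}
        n = None
        for name in PARAM_NAMES:
            a = np.atleast_1d(np.asarray(params[name], dtype=float))
            if n is None:
                n = len(a)
            elif len(a) != n:
                raise ValueError("all parameter arrays must have equal length")
            arrays[name] = a
        self._p = arrays
        if np.any(self.w < 0):
            raise ValueError("weights must be >= 0")
        if np.any(self.d_par > self.d0) or np.any(self.d_perp > self.d0):
            raise ValueError("d_par and d_perp must not exceed d0")

    def __getattr__(self, name):
        try:
            return self.__dict__["_p"][name]
        except KeyError:
            raise AttributeError(name) from None

    @classmethod
    def from_components(cls, components: Iterable[DiffusionComponent]) -> "VoxelDistribution":
        comps = list(components)
        if not comps:
            return cls.empty()
        return cls(**{
            name: np.array([getattr(c, name) for c in comps]) for name in PARAM_NAMES
        })

    @classmethod
    def empty(cls) -> "VoxelDistribution":
        return cls(**{name: np.empty(0) for name in PARAM_NAMES})

    def __len__(self) -> int:
        return len(self._p["w"])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> DiffusionComponent:
        return DiffusionComponent(**{name: float(self._p[name][i]) for name in PARAM_NAMES})

    @property
    def components(self) -> list[DiffusionComponent]:
        return list(self)

    @property
    def total_weight(self) -> float:
        return float(self._p["w"].sum())

    def select(self, mask) -> "VoxelDistribution":
        return VoxelDistribution(**{k: v[mask] for k, v in self._p.items()})

    def with_weights(self, w) -> "VoxelDistribution":
        out = dict(self._p)
        out["w"] = np.asarray(w, dtype=float)
        return VoxelDistribution(**out)

    def principal_axes(self) -> np.ndarray:
        """(n, 3) unit principal axes."""
        st, ct = np.sin(self.theta), np.cos(self.theta)
        return np.column_stack([st * np.cos(self.phi), st * np.sin(self.phi), ct])

    def diffusivities(self, omega) -> tuple[np.ndarray, np.ndarray]:
        """(D∥(ω), D⊥(ω)) arrays; omega broadcasts against components."""
        om = np.asarray(omega, dtype=float)
        d_par = self.d0 - (self.d0 - self.d_par) / (1.0 + (om / self.gamma_par) ** 2)
        d_perp = self.d0 - (self.d0 - self.d_perp) / (1.0 + (om / self.gamma_perp) ** 2)
        return d_par, d_perp

    def iso_anisotropy(self, omega) -> tuple[np.ndarray, np.ndarray]:
        """(Diso(ω), DΔ(ω)) arrays."""
        d_par, d_perp = self.diffusivities(omega)
        d_iso = (d_par + 2.0 * d_perp) / 3.0
        return d_iso, (d_par - d_perp) / (3.0 * d_iso)

    def lab_tensors(self, omega) -> np.ndarray:
        """(n, 3, 3) lab-frame tensors at a scalar ω."""
        d_par, d_perp = self.diffusivities(float(omega))
        u = self.principal_axes()
        return (
            d_perp[:, None, None] * np.eye(3)[None]
            + (d_par - d_perp)[:, None, None] * np.einsum("ia,ib->iab", u, u)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"VoxelDistribution({len(self)} components, total weight {self.total_weight:.4g})"


def _attenuation_exponents(
    dist: VoxelDistribution, spectra: Sequence[EncodingSpectrum]
) -> np.ndarray:
    """β[m, i] = ∫ b_m(ω):D_i(ω) dω by quadrature on each spectrum's grid.

    Uses the axisymmetric contraction b:D = D⊥·tr(b) + (D∥-D⊥)·u^T b u so the
    cost is linear in spectral nodes.
    """
    n_meas = len(spectra)
    u = dist.principal_axes()  # (n, 3)
    beta = np.zeros((n_meas, len(dist)))
    # group spectra by node count so same-size spectra evaluate in one shot
    sizes: dict[int, list[int]] = {}
    for m, sp in enumerate(spectra):
        sizes.setdefault(len(sp.omega), []).append(m)
    for size, rows in sizes.items():
        omega = np.stack([spectra[m].omega for m in rows])          # (M, K)
        wdens = np.stack(
            [spectra[m].weights[:, None, None] * spectra[m].density for m in rows]
        )                                                            # (M, K, 3, 3)
        tr = np.trace(wdens, axis1=2, axis2=3)                       # (M, K)
        ubu = np.einsum("mkab,ia,ib->mki", wdens, u, u)              # (M, K, n)
        om = omega[..., None]                                        # (M, K, 1)
        d_par = dist.d0 - (dist.d0 - dist.d_par) / (1.0 + (om / dist.gamma_par) ** 2)
        d_perp = dist.d0 - (dist.d0 - dist.d_perp) / (1.0 + (om / dist.gamma_perp) ** 2)
        beta[rows] = np.sum(d_perp * tr[..., None] + (d_par - d_perp) * ubu, axis=1)
    return beta


def signal_matrix(
    dist: VoxelDistribution,
    protocol: Protocol,
    spectra: Sequence[EncodingSpectrum],
) -> np.ndarray:
    """Unit-weight signal kernel, shape (n_meas, n_components).

    ``signal_matrix(dist, protocol, spectra) @ dist.w`` is the voxel signal.
    """
    if len(spectra) != len(protocol):
        raise ValueError("one spectrum per protocol point required")
    if len(dist) == 0:
        return np.zeros((len(protocol), 0))
    beta = _attenuation_exponents(dist, spectra)
    tau_R = protocol.column("tau_R")[:, None]
    tau_E = protocol.column("tau_E")[:, None]
    relax = (1.0 - np.exp(-tau_R * dist.r1[None])) * np.exp(-tau_E * dist.r2[None])
    return np.exp(-beta) * relax


def signal(
    distribution: VoxelDistribution | Iterable[DiffusionComponent],
    point: AcquisitionPoint,
    spectrum: EncodingSpectrum,
    b_rtol: float = 1e-3,
) -> float:
    """Signal amplitude of a voxel distribution for one acquisition point.

    Raises
    ------
    InconsistentEncodingError
        If the spectrum's integrated b differs from ``point.b`` beyond
        ``b_rtol`` relative tolerance.
    """
    if not isinstance(distribution, VoxelDistribution):
        distribution = VoxelDistribution.from_components(distribution)
    b_ref = max(point.b, 1.0)
    if abs(spectrum.b - point.b) > b_rtol * b_ref:
        raise InconsistentEncodingError(
            f"spectrum b={spectrum.b:.6g} does not match point b={point.b:.6g}"
        )
    live = distribution.select(distribution.w > 0)
    if len(live) == 0:
        return 0.0
    protocol = Protocol.from_points([point])
    return float((signal_matrix(live, protocol, [spectrum]) @ live.w)[0])
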