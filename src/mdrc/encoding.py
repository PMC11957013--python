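"""Diffusion encoding waveforms, tensor-valued encoding spectra b(ω), and
protocol frequency summaries.

A measurement's diffusion sensitization is described by the tensor-valued
spectral density b(ω) of its dephasing vector q(t): the signal attenuation of
a component with diffusion spectrum D(ω) is exp(-∫ b(ω):D(ω) dω).  Spectra
are stored one-sided (ω ≥ 0) with the negative-frequency half folded in,
which is lossless because D(ω) is even in ω.

Frequencies are handled in angular units (rad/s) internally; every
user-facing frequency (protocol tables, centroids, percentiles) is ω/2π in
Hz, matching the conventions of the oscillating-gradient literature.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GYROMAGNETIC_RATIO_1H",
    "AcquisitionPoint",
    "Protocol",
    "EncodingSpectrum",
    "build_waveform",
    "spectrum_from_waveform",
    "delta_spectrum",
    "delta_spectra",
    "centroid_frequency",
    "b_weighted_frequency_percentiles",
    "protocol_frequency_band",
    "make_default_protocol",
    "make_desk_protocol",
    "InvalidWaveformError",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GYROMAGNETIC_RATIO_1H = 2.6752218744e8

PROTOCOL_COLUMNS = [
    "b",
    "b_delta",
    "theta",
    "phi",
    "omega_cent",
    "tau_R",
    "tau_E",
    "modulation_order",
]


class InvalidWaveformError(ValueError):
    """Waveform violates the echo condition (nonzero residual dephasing)."""


@dataclass(frozen=True)
class AcquisitionPoint:
    """Encoding settings of a single image in the acquisition protocol.

    Parameters
    ----------
    b : float
        Total b-value, s m^-2.
    b_delta : float
        Normalized b-tensor shape in [-0.5, 1] (-0.5 planar, 0 spherical,
        1 linear).
    theta, phi : float
        Polar/azimuthal orientation of the encoding tensor symmetry axis, rad.
    omega_cent : float
        Centroid frequency of the encoding spectrum, Hz.
    tau_R : float
        Repetition time (saturation to excitation), s.
    tau_E : float
        Echo time, s.
    modulation_order : int
        Gradient waveform modulation order, 0-2.
    """

    b: float
    b_delta: float = 1.0
    theta: float = 0.0
    phi: float = 0.0
    omega_cent: float = 0.0
    tau_R: float = 3.5
    tau_E: float = 0.0094
    modulation_order: int = 0

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if not -0.5 <= self.b_delta <= 1.0:
            raise ValueError(f"b_delta must be in [-0.5, 1], got {self.b_delta}")
        if self.tau_E <= 0:
            raise ValueError(f"tau_E must be > 0, got {self.tau_E}")
        if self.tau_R <= 0:
            raise ValueError(f"tau_R must be > 0, got {self.tau_R}")
        if self.omega_cent < 0:
            raise ValueError(f"omega_cent must be >= 0, got {self.omega_cent}")
        if int(self.modulation_order) not in (0, 1, 2):
            raise ValueError(
                f"modulation_order must be 0, 1 or 2, got {self.modulation_order}"
            )


class Protocol:
    """Ordered table of :class:`AcquisitionPoint` settings.

    Wraps a :class:`pandas.DataFrame` with columns ``b, b_delta, theta, phi,
    omega_cent, tau_R, tau_E, modulation_order`` (SI units, omega_cent in Hz).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in PROTOCOL_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"protocol table missing columns: {missing}")
        table = table[PROTOCOL_COLUMNS].reset_index(drop=True)
        # validate every row through the dataclass invariants
        for row in table.itertuples(index=False):
            AcquisitionPoint(*row)
        self.table = table

    @classmethod
    def from_points(cls, points: Iterable[AcquisitionPoint]) -> "Protocol":
        rows = [
            (p.b, p.b_delta, p.theta, p.phi, p.omega_cent, p.tau_R, p.tau_E,
             int(p.modulation_order))
            for p in points
        ]
        return cls(pd.DataFrame(rows, columns=PROTOCOL_COLUMNS))

    @classmethod
    def from_csv(cls, path) -> "Protocol":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_json(cls, path) -> "Protocol":
        if isinstance(path, (str, bytes)) and not str(path).lstrip().startswith("["):
            with open(path) as fh:
                records = json.load(fh)
        else:
            records = json.load(_io.StringIO(path))
        return cls(pd.DataFrame.from_records(records))

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[AcquisitionPoint]:
        for row in self.table.itertuples(index=False):
            yield AcquisitionPoint(*row)

    def __getitem__(self, i: int) -> AcquisitionPoint:
        return AcquisitionPoint(*self.table.iloc[i])

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    def subset(self, rows: Sequence[int]) -> "Protocol":
        return Protocol(self.table.iloc[list(rows)])

    def __repr__(self) -> str:  # pragma: no cover
        b = self.column("b")
        return (
            f"Protocol({len(self)} points, b {b.min():.3g}-{b.max():.3g} s/m^2, "
            f"omega_cent {self.column('omega_cent').min():.3g}-"
            f"{self.column('omega_cent').max():.3g} Hz)"
        )


@dataclass
class EncodingSpectrum:
    """One-sided discretized tensor-valued encoding spectral density.

    Attributes
    ----------
    omega : ndarray, shape (n,)
        Nonnegative angular frequencies, rad/s, ascending.
    density : ndarray, shape (n, 3, 3)
        Symmetric PSD spectral-density tensors, s m^-2 per rad/s, with the
        negative-frequency half already folded in.
    weights : ndarray, shape (n,)
        Quadrature weights (rad/s) such that ``einsum('k,kij->ij', weights,
        density)`` is the integrated b-tensor.  A single-node spectrum with
        weight 1 represents an idealized delta spectrum (all encoding power
        at ± its node frequency).
    """

    omega: np.ndarray
    density: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.density = np.asarray(self.density, dtype=float).reshape(-1, 3, 3)
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if not (len(self.omega) == len(self.density) == len(self.weights)):
            raise ValueError("omega, density and weights must have equal length")
        if np.any(self.omega < 0):
            raise ValueError("one-sided spectrum requires omega >= 0")

    @property
    def btensor(self) -> np.ndarray:
        """Integrated 3x3 b-tensor, s m^-2."""
        return np.einsum("k,kij->ij", self.weights, self.density)

    @property
    def b(self) -> float:
        """Integrated trace (conventional b-value), s m^-2."""
        return float(np.trace(self.btensor))


def build_waveform(
    modulation_order: int,
    duration: float,
    n_samples: int = 512,
    axis_weights: Sequence[float] = (1.0, 0.0, 0.0),
    amplitude: float = 0.5,
    gyromagnetic_ratio: float = GYROMAGNETIC_RATIO_1H,
) -> np.ndarray:
    """Synthesize a 3-axis gradient waveform with controllable frequency content.

    The waveform family is a documented stand-in for modulated encoding
    gradients: on each active axis the dephasing vector follows a Hann-windowed
    oscillation ``q(t) ∝ sin²(πτ/T_s)·cos(2πmτ/T_s)`` with ``m`` full
    oscillations for modulation order ``m``, so higher orders concentrate
    encoding power at higher frequency.  The three axes are multiplexed into
    disjoint time slots; cross-axis moments therefore vanish exactly and equal
    ``axis_weights`` yield a spherical (b_delta = 0) b-tensor.

    Parameters
    ----------
    modulation_order : int
        0, 1 or 2.
    duration : float
        Total waveform duration, s.
    n_samples : int
        Samples over the full duration (>= 16).
    axis_weights : sequence of 3 floats
        Relative q amplitude per lab axis; zero disables an axis.
    amplitude : float
        Peak gradient scale, T/m.

    Returns
    -------
    ndarray, shape (3, n_samples)
        Gradient waveform g(t), T/m, with zero net zeroth moment per axis.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if int(modulation_order) not in (0, 1, 2):
        raise ValueError(f"unsupported modulation order {modulation_order}")
    if n_samples < 16:
        raise ValueError(f"n_samples must be >= 16, got {n_samples}")
    axis_weights = np.asarray(axis_weights, dtype=float)
    if axis_weights.shape != (3,):
        raise ValueError("axis_weights must be a 3-vector")

    m = int(modulation_order)
    t = np.linspace(0.0, duration, n_samples)
    active = np.flatnonzero(axis_weights != 0)
    n_slots = max(len(active), 1)
    slot_len = duration / n_slots
    # q target amplitude from gradient scale: q ~ gamma * A * slot_len
    q0 = gyromagnetic_ratio * amplitude * slot_len / (2.0 * np.pi * max(m, 1))

    q = np.zeros((3, n_samples))
    for slot, ax in enumerate(active):
        t0 = slot * slot_len
        tau = (t - t0) / slot_len
        inside = (tau >= 0.0) & (tau <= 1.0)
        window = np.sin(np.pi * tau) ** 2
        carrier = np.cos(2.0 * np.pi * m * tau)
        q[ax, inside] = (axis_weights[ax] * q0 * window * carrier)[inside]
    g = np.gradient(q, t, axis=1) / gyromagnetic_ratio
    # enforce the echo condition exactly in the sampled gradient
    g -= np.trapezoid(g, t, axis=1)[:, None] / duration
    return g


def spectrum_from_waveform(
    waveform: np.ndarray,
    dt: float,
    gyromagnetic_ratio: float = GYROMAGNETIC_RATIO_1H,
    dephasing_tol: float = 1e-3,
) -> EncodingSpectrum:
    """Compute the one-sided tensor-valued encoding spectrum of a gradient waveform.

    The dephasing vector q(t) = γ∫g dt is Fourier transformed; the spectral
    density is b(ω) = Re[q̃(ω) q̃(ω)^H] / 2π, folded one-sided.  By the discrete
    Parseval identity the quadrature-integrated trace equals the time-domain
    b-value Σ|q|²dt exactly.

    Parameters
    ----------
    waveform : ndarray, shape (3, n)
        Gradient waveform, T/m.
    dt : float
        Sample interval, s.
    dephasing_tol : float
        Maximum allowed |q(T)| relative to max|q(t)|.
    """
    g = np.atleast_2d(np.asarray(waveform, dtype=float))
    if g.shape[0] != 3:
        raise ValueError("waveform must have shape (3, n_samples)")
    n = g.shape[1]
    # cumulative trapezoid for q(t)
    q = np.concatenate(
        [np.zeros((3, 1)), np.cumsum(0.5 * (g[:, 1:] + g[:, :-1]) * dt, axis=1)],
        axis=1,
    ) * gyromagnetic_ratio
    qmax = np.abs(q).max()
    if qmax > 0 and np.abs(q[:, -1]).max() > dephasing_tol * qmax:
        raise InvalidWaveformError(
            "waveform does not refocus: residual dephasing "
            f"{np.abs(q[:, -1]).max() / qmax:.2e} exceeds tolerance {dephasing_tol}"
        )

    qf = np.fft.rfft(q, axis=1) * dt  # continuous-FT approximation
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, d=dt)
    density = np.real(np.einsum("ak,bk->kab", qf, qf.conj())) / (2.0 * np.pi)
    d_omega = 2.0 * np.pi / (n * dt)
    fold = np.full(len(omega), 2.0)
    fold[0] = 1.0
    if n % 2 == 0:
        fold[-1] = 1.0
    return EncodingSpectrum(omega=omega, density=density, weights=fold * d_omega)


def _axisymmetric_btensor(b: float, b_delta: float, theta: float, phi: float) -> np.ndarray:
    """b-tensor with trace b, shape b_delta, symmetry axis (theta, phi)."""
    u = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    iso = np.eye(3) / 3.0
    return b * (iso + b_delta * (np.outer(u, u) - iso))


def delta_spectrum(point: AcquisitionPoint) -> EncodingSpectrum:
    """Idealized spectrum placing all encoding power at ±ωcent.

    Makes the attenuation integral closed-form:
    ∫b(ω):D(ω)dω = b_tensor : D(ω_cent).
    """
    bt = _axisymmetric_btensor(point.b, point.b_delta, point.theta, point.phi)
    return EncodingSpectrum(
        omega=np.array([2.0 * np.pi * point.omega_cent]),
        density=bt[None],
        weights=np.array([1.0]),
    )


def delta_spectra(protocol: Protocol) -> list[EncodingSpectrum]:
    """Delta spectra for every protocol point."""
    return [delta_spectrum(p) for p in protocol]


def centroid_frequency(spectrum: EncodingSpectrum) -> float:
    """Power-weighted mean of |ω|/2π over the spectral-density trace, Hz."""
    power = spectrum.weights * np.trace(spectrum.density, axis1=1, axis2=2)
    total = power.sum()
    if total <= 0:
        raise ValueError("zero-power spectrum has no centroid frequency")
    return float((power * spectrum.omega).sum() / total / (2.0 * np.pi))


def b_weighted_frequency_percentiles(
    protocol: Protocol | Sequence[AcquisitionPoint],
    percentiles: Sequence[float],
) -> np.ndarray:
    """Percentiles of the protocol's ωcent values weighted by b-value, Hz.

    Weighting by b effectively excludes low-b images from the frequency
    distribution.  Uses the weighted step-CDF estimator: the p-th percentile
    is the smallest ωcent whose cumulative b-weight reaches p.
    """
    if not isinstance(protocol, Protocol):
        protocol = Protocol.from_points(protocol)
    b = protocol.column("b")
    w_cent = protocol.column("omega_cent")
    if not np.any(b > 0):
        raise ValueError("b-weighted frequency distribution undefined: all b = 0")
    order = np.argsort(w_cent, kind="stable")
    w_cent, b = w_cent[order], b[order]
    cdf = np.cumsum(b) / b.sum()
    p = np.asarray(percentiles, dtype=float) / 100.0
    idx = np.searchsorted(cdf, p, side="left")
    return w_cent[np.clip(idx, 0, len(w_cent) - 1)]


def protocol_frequency_band(protocol: Protocol) -> tuple[float, float]:
    """(ωmin, ωmax) in rad/s: the 10th/90th b-weighted percentiles of ωcent.

    This band is the default frequency pair for the Δω/2π restriction metrics.
    """
    lo, hi = b_weighted_frequency_percentiles(protocol, [10.0, 90.0])
    return 2.0 * np.pi * float(lo), 2.0 * np.pi * float(hi)


def _sphere_directions(n: int) -> np.ndarray:
    """n quasi-uniform directions (golden-spiral) as (theta, phi) pairs."""
    i = np.arange(n) + 0.5
    theta = np.arccos(1.0 - 2.0 * i / n)
    phi = np.mod(np.pi * (1.0 + np.sqrt(5.0)) * i, 2.0 * np.pi)
    return np.column_stack([theta, phi])


def _protocol_rows(
    b_values: np.ndarray,
    omega_by_order: dict[int, float],
    n_dir_linear: int,
    n_dir_planar: int,
    tau_E_range: tuple[float, float],
    tau_R_values: Sequence[float],
    n_relax_E: int,
    n_relax_R: int,
) -> pd.DataFrame:
    rows = []
    tE_lo, tE_hi = tau_E_range
    # relaxation block: b = 0 images crossing tau_E and tau_R
    for tE in np.linspace(tE_lo, tE_hi, n_relax_E):
        for tR in np.linspace(min(tau_R_values), max(tau_R_values), n_relax_R):
            rows.append((0.0, 0.0, 0.0, 0.0, min(omega_by_order.values()), tR, tE, 0))
    # diffusion blocks: orders x shapes x b x orientation
    for order, f_cent in omega_by_order.items():
        for b_delta, n_dir in ((1.0, n_dir_linear), (0.0, 1), (-0.5, n_dir_planar)):
            dirs = _sphere_directions(n_dir)
            for b in b_values:
                # longer echo time needed to reach higher b
                tE = tE_lo + (tE_hi - tE_lo) * b / b_values.max()
                tR = tau_R_values[int(b * 7919) % len(tau_R_values)]
                for theta, phi in dirs:
                    rows.append((b, b_delta, theta, phi, f_cent, tR, tE, order))
    return pd.DataFrame(rows, columns=PROTOCOL_COLUMNS)


def make_default_protocol() -> Protocol:
    """Default acquisition protocol spanning the study's parameter ranges.

    b from 0 to 8e9 s m^-2, echo time 9.4-49.4 ms, repetition time 0.8-3.5 s,
    centroid frequencies 36.6-247 Hz across modulation orders 0-2, b-tensor
    shapes linear/spherical/planar (~350 images).
    """
    table = _protocol_rows(
        b_values=np.array([0.5, 1.0, 2.0, 3.5, 5.5, 8.0]) * 1e9,
        omega_by_order={0: 36.6, 1: 130.0, 2: 247.0},
        n_dir_linear=10,
        n_dir_planar=6,
        tau_E_range=(9.4e-3, 49.4e-3),
        tau_R_values=(0.8, 1.5, 2.5, 3.5),
        n_relax_E=7,
        n_relax_R=7,
    )
    return Protocol(table)


def make_desk_protocol() -> Protocol:
    """Reduced protocol (~200 images) with the same parameter coverage.

    Intended for synthetic experiments and tests where inversion runtime
    matters more than angular resolution.
    """
    table = _protocol_rows(
        b_values=np.array([0.5, 1.5, 3.5, 8.0]) * 1e9,
        omega_by_order={0: 36.6, 1: 130.0, 2: 247.0},
        n_dir_linear=8,
        n_dir_planar=4,
        tau_E_range=(9.4e-3, 49.4e-3),
        tau_R_values=(0.8, 1.5, 2.5, 3.5),
        n_relax_E=7,
        n_relax_R=7,
    )
    return Protocol(table)
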