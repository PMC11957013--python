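"""Monte Carlo bootstrap inversion of voxel signals into component ensembles.

The inverse problem — decompose a voxel signal into nonnegative-weight
D(ω)-R1-R2 components — is ill-posed, so instead of a single best fit the
solver draws random candidate components inside hard parameter limits, fits
their weights by nonnegative least squares (NNLS), and iteratively refines
the surviving components with shrinking log-space perturbations.  Repeating
the fit on bootstrap resamples of the acquisition yields an ensemble of
plausible solutions per voxel whose spread reflects solution-space
uncertainty.

All randomness flows from one seed; per-voxel substreams are derived by
voxel counter so results are independent of processing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .encoding import EncodingSpectrum, Protocol, delta_spectra
from .forward import VoxelDistribution, signal_matrix

__all__ = [
    "InversionLimits",
    "InversionConfig",
    "VoxelFit",
    "VoxelEnsemble",
    "sample_components",
    "sample_component",
    "fit_weights",
    "invert_voxel",
    "bootstrap_ensemble",
    "MonteCarloInverter",
    "voxel_rng",
]


@dataclass(frozen=True)
class InversionLimits:
    """Hard box limits of the solution space.

    Defaults are the study's stated limits: 5e-12 < D0/D⊥/D∥ < 5e-9 m²/s,
    0.1 < Γ⊥/Γ∥ < 1e5 1/s, 0.1 < R1 < 4 1/s, 4 < R2 < 100 1/s.
    """

    d_min: float = 5e-12
    d_max: float = 5e-9
    gamma_min: float = 0.1
    gamma_max: float = 1e5
    r1_min: float = 0.1
    r1_max: float = 4.0
    r2_min: float = 4.0
    r2_max: float = 100.0

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.d_min, self.d_max, "D"),
            (self.gamma_min, self.gamma_max, "Gamma"),
            (self.r1_min, self.r1_max, "R1"),
            (self.r2_min, self.r2_max, "R2"),
        ):
            if not (0 < lo < hi):
                raise ValueError(f"{name} range must satisfy 0 < lower < upper")

    def contains(self, dist: VoxelDistribution, atol_rel: float = 1e-12) -> bool:
        """True if every component of ``dist`` lies inside the limits."""
        def inside(x, lo, hi):
            tol = atol_rel * hi
            return np.all(x >= lo - tol) and np.all(x <= hi + tol)

        return bool(
            inside(dist.d0, self.d_min, self.d_max)
            and inside(dist.d_par, self.d_min, self.d_max)
            and inside(dist.d_perp, self.d_min, self.d_max)
            and inside(dist.gamma_par, self.gamma_min, self.gamma_max)
            and inside(dist.gamma_perp, self.gamma_min, self.gamma_max)
            and inside(dist.r1, self.r1_min, self.r1_max)
            and inside(dist.r2, self.r2_min, self.r2_max)
        )


@dataclass(frozen=True)
class InversionConfig:
    """Monte Carlo inversion algorithm settings (all stand-ins, none fixed by
    the acquisition: counts trade accuracy for runtime).

    Parameters
    ----------
    n_candidates : int
        Initial random components per fit (N_in).
    n_refine : int
        Mutation + NNLS refinement rounds (R).
    n_children : int
        Mutated copies proposed per surviving component per round.
    n_fresh : int
        Fresh random components injected per round (escape local optima).
    max_components : int
        Final cap on nonzero-weight components.
    n_bootstrap : int
        Bootstrap replicates per voxel (>= 2 for ensembles).
    mutation_scale, mutation_scale_final : float
        Log-space perturbation s.d. of the first/last refinement round
        (geometrically interpolated).
    """

    n_candidates: int = 500
    n_refine: int = 40
    n_children: int = 5
    n_fresh: int = 60
    max_components: int = 10
    n_bootstrap: int = 64
    mutation_scale: float = 0.5
    mutation_scale_final: float = 0.01


@dataclass
class VoxelFit:
    """One inversion solution: a component distribution plus fit residuals."""

    distribution: VoxelDistribution
    residual: float
    residual_initial: float


@dataclass
class VoxelEnsemble:
    """Bootstrap ensemble of candidate solutions for one voxel."""

    solutions: list[VoxelDistribution]
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)

    def component_counts(self) -> np.ndarray:
        return np.array([np.count_nonzero(s.w) for s in self.solutions])


def voxel_rng(seed: int | None, index: int) -> np.random.Generator:
    """Deterministic per-voxel substream derived from a base seed by counter."""
    if seed is None:
        seed = 0
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(index,)))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_components(
    limits: InversionLimits, n: int, rng
) -> VoxelDistribution:
    """Draw ``n`` unit-weight random components inside the limits.

    Diffusivities and transition frequencies are log-uniform (the limits span
    decades); D0 is the largest of three log-uniform draws and the remaining
    two are assigned to D∥/D⊥ in random order, enforcing D∥, D⊥ <= D0 by
    reordering.  Orientations are uniform on the sphere; R1, R2 uniform.
    """
    rng = _as_rng(rng)
    log_d = rng.uniform(np.log(limits.d_min), np.log(limits.d_max), size=(n, 3))
    # put the max in column 0 (D0); shuffle the other two per row
    order = np.argsort(log_d, axis=1)[:, ::-1]
    log_d = np.take_along_axis(log_d, order, axis=1)
    swap = rng.random(n) < 0.5
    log_d[swap, 1], log_d[swap, 2] = log_d[swap, 2], log_d[swap, 1].copy()
    d0, d_par, d_perp = np.exp(log_d).T
    gammas = np.exp(
        rng.uniform(np.log(limits.gamma_min), np.log(limits.gamma_max), size=(n, 2))
    )
    cos_t = rng.uniform(-1.0, 1.0, size=n)
    theta = np.arccos(cos_t)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    r1 = rng.uniform(limits.r1_min, limits.r1_max, size=n)
    r2 = rng.uniform(limits.r2_min, limits.r2_max, size=n)
    return VoxelDistribution(
        d0=d0, d_par=d_par, d_perp=d_perp,
        gamma_par=gammas[:, 0], gamma_perp=gammas[:, 1],
        theta=theta, phi=phi, r1=r1, r2=r2, w=np.ones(n),
    )


def sample_component(limits: InversionLimits, rng):
    """Draw a single unit-weight random component (see :func:`sample_components`)."""
    return sample_components(limits, 1, rng)[0]


def fit_weights(
    components: VoxelDistribution,
    signals: np.ndarray,
    protocol: Protocol,
    spectra: Sequence[EncodingSpectrum],
) -> tuple[np.ndarray, float]:
    """Nonnegative least-squares weights for a fixed component basis.

    Returns
    -------
    weights : ndarray
        Nonnegative weights, one per component.
    residual : float
        L2 norm of the signal misfit.
    """
    if len(components) == 0:
        raise ValueError("component basis is empty")
    y = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("signals must be finite")
    kernel = signal_matrix(components, protocol, spectra)
    w, res = nnls(kernel, y)
    return w, float(res)


def _mutate(
    dist: VoxelDistribution,
    limits: InversionLimits,
    scale: float,
    rng: np.random.Generator,
) -> VoxelDistribution:
    """Log-space perturbation of each component, clipped back into limits."""
    n = len(dist)

    def jog_log(x, lo, hi):
        return np.clip(x * np.exp(rng.normal(0.0, scale, n)), lo, hi)

    d0 = jog_log(dist.d0, limits.d_min, limits.d_max)
    d_par = np.minimum(jog_log(dist.d_par, limits.d_min, limits.d_max), d0)
    d_perp = np.minimum(jog_log(dist.d_perp, limits.d_min, limits.d_max), d0)
    gamma_par = jog_log(dist.gamma_par, limits.gamma_min, limits.gamma_max)
    gamma_perp = jog_log(dist.gamma_perp, limits.gamma_min, limits.gamma_max)
    r1 = np.clip(
        dist.r1 + rng.normal(0.0, scale, n) * (limits.r1_max - limits.r1_min) / 2.0,
        limits.r1_min, limits.r1_max,
    )
    r2 = np.clip(
        dist.r2 + rng.normal(0.0, scale, n) * (limits.r2_max - limits.r2_min) / 2.0,
        limits.r2_min, limits.r2_max,
    )
    # perturb the principal axis tangentially and renormalize
    u = dist.principal_axes() + rng.normal(0.0, scale, (n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2.0 * np.pi)
    return VoxelDistribution(
        d0=d0, d_par=d_par, d_perp=d_perp, gamma_par=gamma_par,
        gamma_perp=gamma_perp, theta=theta, phi=phi, r1=r1, r2=r2,
        w=np.ones(n),
    )


def _concat(a: VoxelDistribution, b: VoxelDistribution) -> VoxelDistribution:
    return VoxelDistribution(**{
        name: np.concatenate([getattr(a, name), getattr(b, name)])
        for name in ("d0", "d_par", "d_perp", "gamma_par", "gamma_perp",
                     "theta", "phi", "r1", "r2", "w")
    })


def invert_voxel(
    signals: np.ndarray,
    protocol: Protocol,
    spectra: Sequence[EncodingSpectrum],
    limits: InversionLimits | None = None,
    config: InversionConfig | None = None,
    rng=None,
) -> VoxelFit:
    """Monte Carlo inversion of one voxel's signals.

    Random candidate components are weighted by NNLS; the nonzero-weight
    survivors are refined for ``config.n_refine`` rounds by proposing
    perturbed copies and refitting the joint basis (the parents stay in the
    basis, so the residual is non-increasing by construction).  The final
    solution is pruned to ``config.max_components`` components.
    """
    limits = limits or InversionLimits()
    config = config or InversionConfig()
    rng = _as_rng(rng)
    y = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("signals must be finite")
    if len(y) != len(protocol):
        raise ValueError("signals length must match protocol length")

    basis = sample_components(limits, config.n_candidates, rng)
    w, res = fit_weights(basis, y, protocol, spectra)
    res_initial = res
    survivors = basis.select(w > 0).with_weights(w[w > 0])

    n_refine = config.n_refine
    for r in range(n_refine):
        if len(survivors) == 0:
            break
        frac = r / max(n_refine - 1, 1)
        scale = config.mutation_scale * (
            config.mutation_scale_final / config.mutation_scale
        ) ** frac
        pool = survivors
        for _ in range(config.n_children):
            pool = _concat(pool, _mutate(survivors, limits, scale, rng))
        if config.n_fresh > 0:
            pool = _concat(pool, sample_components(limits, config.n_fresh, rng))
        w, res_new = fit_weights(pool, y, protocol, spectra)
        keep = w > 0
        if keep.any() and res_new <= res:
            survivors = pool.select(keep).with_weights(w[keep])
            res = res_new

    if len(survivors) > config.max_components:
        top = np.argsort(survivors.w)[::-1][: config.max_components]
        survivors = survivors.select(np.sort(top))
        w, res = fit_weights(survivors, y, protocol, spectra)
        survivors = survivors.with_weights(w)
        live = survivors.w > 0
        survivors = survivors.select(live)
    return VoxelFit(distribution=survivors, residual=res, residual_initial=res_initial)


def bootstrap_ensemble(
    signals: np.ndarray,
    protocol: Protocol,
    spectra: Sequence[EncodingSpectrum],
    limits: InversionLimits | None = None,
    config: InversionConfig | None = None,
    rng=None,
) -> VoxelEnsemble:
    """Bootstrap ensemble of Monte Carlo solutions for one voxel.

    Each replicate resamples protocol rows with replacement (full size) and
    re-runs :func:`invert_voxel` on the resampled design.
    """
    limits = limits or InversionLimits()
    config = config or InversionConfig()
    if config.n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2 for an ensemble")
    rng = _as_rng(rng)
    y = np.asarray(signals, dtype=float)
    n = len(protocol)
    solutions, residuals = [], []
    for _ in range(config.n_bootstrap):
        rows = rng.integers(0, n, size=n)
        sub_protocol = protocol.subset(rows)
        sub_spectra = [spectra[i] for i in rows]
        fit = invert_voxel(y[rows], sub_protocol, sub_spectra, limits, config, rng)
        solutions.append(fit.distribution)
        residuals.append(fit.residual)
    return VoxelEnsemble(solutions=solutions, residuals=np.asarray(residuals))


class MonteCarloInverter(BaseEstimator):
    """Scikit-learn style estimator wrapping the Monte Carlo inversion.

    Parameters
    ----------
    protocol : Protocol
        Acquisition protocol (one row per signal sample).
    spectra : sequence of EncodingSpectrum, optional
        Encoding spectra per protocol row; defaults to idealized delta
        spectra at each row's centroid frequency.
    limits : InversionLimits, optional
    n_candidates, n_refine, max_components : int
        See :class:`InversionConfig`.
    bootstrap : bool
        If True, fit a bootstrap ensemble per voxel (``ensembles_``).
    n_bootstrap : int
        Replicates per voxel when ``bootstrap`` is enabled.
    random_state : int, optional
        Base seed; voxel substreams are derived by counter.

    Attributes
    ----------
    distributions_ : list of VoxelDistribution
        One consolidated best-fit solution per voxel (row of X).
    residuals_ : ndarray
        Final fit residual per voxel.
    ensembles_ : list of VoxelEnsemble
        Only when ``bootstrap=True``.
    """

    def __init__(
        self,
        protocol=None,
        spectra=None,
        limits=None,
        n_candidates: int = 200,
        n_refine: int = 20,
        max_components: int = 10,
        bootstrap: bool = False,
        n_bootstrap: int = 64,
        random_state: int | None = None,
    ):
        self.protocol = protocol
        self.spectra = spectra
        self.limits = limits
        self.n_candidates = n_candidates
        self.n_refine = n_refine
        self.max_components = max_components
        self.bootstrap = bootstrap
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def _config(self) -> InversionConfig:
        return InversionConfig(
            n_candidates=self.n_candidates,
            n_refine=self.n_refine,
            max_components=self.max_components,
            n_bootstrap=self.n_bootstrap,
        )

    def fit(self, X, y=None):
        """Invert each row of ``X`` (n_voxels, n_measurements)."""
        if self.protocol is None:
            raise ValueError("MonteCarloInverter requires a protocol")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None]
        if X.shape[1] != len(self.protocol):
            raise ValueError(
                f"X has {X.shape[1]} measurements but protocol has {len(self.protocol)}"
            )
        spectra = self.spectra if self.spectra is not None else delta_spectra(self.protocol)
        limits = self.limits or InversionLimits()
        config = self._config()
        self.distributions_, residuals = [], []
        self.ensembles_ = [] if self.bootstrap else None
        for i, row in enumerate(X):
            rng = voxel_rng(self.random_state, i)
            fit = invert_voxel(row, self.protocol, spectra, limits, config, rng)
            self.distributions_.append(fit.distribution)
            residuals.append(fit.residual)
            if self.bootstrap:
                rng_b = voxel_rng(self.random_state, i + 2**20)
                self.ensembles_.append(
                    bootstrap_ensemble(row, self.protocol, spectra, limits, config, rng_b)
                )
        self.residuals_ = np.asarray(residuals)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray:
        """Reconstructed signals of the fitted voxels (n_voxels, n_meas)."""
        if not hasattr(self, "distributions_"):
            raise AttributeError("MonteCarloInverter is not fitted")
        spectra = self.spectra if self.spectra is not None else delta_spectra(self.protocol)
        out = np.zeros((len(self.distributions_), len(self.protocol)))
        for i, dist in enumerate(self.distributions_):
            if len(dist):
                out[i] = signal_matrix(dist, self.protocol, spectra) @ dist.w
        return out
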