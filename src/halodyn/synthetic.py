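"""Synthetic data generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure the downstream estimators
assume, so the whole pipeline is testable without instrument or wet-lab data:

* elastic neutron scans from multi-population harmonic scatterers whose mean
  square displacement grows linearly with temperature, with Poisson counting
  noise, an empty-cell background run and a vanadium calibration run;
* survival curves from a two-subpopulation exponential death model with
  multiplicative log-normal noise;
* regrowth curves that stay flat for a lag period and then grow
  exponentially;
* two-channel (SYTO9/PI) cytometry event tables drawn from bivariate
  log-normal mixtures, with the component label kept as a hidden truth
  column;
* linear oxygen-depletion traces with Gaussian sensor noise.

Every generator is deterministic given (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import REFERENCE_MONITOR, TWO_KB_A2_PER_K
from .kinetics import EventTable, GrowthCurve, OxygenTrace
from .reduction import ElasticScanSet

__all__ = [
    "InstrumentConfig",
    "Population",
    "DynamicsModel",
    "RawScanBundle",
    "KillCurveParams",
    "CytometryMixture",
    "MixtureComponent",
    "simulate_elastic_bundle",
    "simulate_kill_curve",
    "simulate_recovery_curve",
    "simulate_cytometry_events",
    "simulate_oxygen_trace",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


def _default_q_grid() -> np.ndarray:
    # accessible momentum-transfer range of a backscattering elastic scan,
    # 0.2-4.9 A^-1 in 0.1 steps
    return np.round(np.arange(0.2, 4.9 + 1e-9, 0.1), 10)


def _default_temperatures() -> np.ndarray:
    # scans above the freezing point of water, 278-315 K
    return np.linspace(278.0, 315.0, 8)


@dataclass
class InstrumentConfig:
    """Elastic-scan instrument description.

    ``resolution_fwhm`` (µeV) is metadata only — no energy axis is
    simulated.  ``detector_efficiency`` may be a scalar or a per-Q array;
    ``monitor`` sets the counting statistics (amplitudes are calibrated to
    counts at the reference monitor of 1e6).
    """

    q_grid: np.ndarray = field(default_factory=_default_q_grid)
    temperatures: np.ndarray = field(default_factory=_default_temperatures)
    resolution_fwhm: float = 8.0
    detector_efficiency: np.ndarray | float = 1.0
    monitor: float = REFERENCE_MONITOR
    transmission: float = 0.90

    def __post_init__(self):
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.q_grid.size == 0:
            raise ValueError("q_grid must be non-empty")
        if np.any(self.q_grid <= 0) or np.any(np.diff(self.q_grid) <= 0):
            raise ValueError("q_grid must be strictly increasing and positive")
        if np.any(self.temperatures <= 0) or np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing and positive")
        if not 0.0 < self.transmission <= 1.0:
            raise ValueError("transmission must be in (0, 1]")
        if not self.monitor > 0:
            raise ValueError("monitor must be positive")
        eff = np.broadcast_to(
            np.asarray(self.detector_efficiency, dtype=float), self.q_grid.shape
        )
        if np.any(eff <= 0):
            raise ValueError("detector_efficiency must be positive")

    @property
    def efficiency(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.detector_efficiency, dtype=float), self.q_grid.shape
        ).astype(float)


@dataclass(frozen=True)
class Population:
    """One harmonic scatterer sub-population.

    ``u2_ref`` is the MSD (Å²) at the reference temperature; ``k_prime``
    (N/m) sets the MSD temperature slope 2·k_B/k'.
    """

    weight: float
    k_prime: float
    u2_ref: float

    def __post_init__(self):
        if not self.k_prime > 0:
            raise ValueError("k_prime must be positive")
        if self.u2_ref < 0:
            raise ValueError("u2_ref must be non-negative")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class DynamicsModel:
    """Generative model for the elastic intensity of a proteome.

    Each population p contributes w_p·exp(-Q²·u²_p(T)/6) with
    u²_p(T) = u2_ref_p + (2·k_B/k'_p)·(T - t_ref); the elastic form factor
    is scaled by ``amplitude`` (counts at the reference monitor) and sits on
    a per-Q additive empty-cell ``background``.
    """

    populations: list
    t_ref: float = 278.0
    amplitude: float = 1.0e4
    background: np.ndarray | float = 500.0

    def __post_init__(self):
        self.populations = [
            p if isinstance(p, Population) else Population(*p) for p in self.populations
        ]
        w = sum(p.weight for p in self.populations)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"population weights must sum to 1 (got {w!r})")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if np.any(np.asarray(self.background, dtype=float) < 0):
            raise ValueError("background must be non-negative")

    def u2(self, temperature) -> np.ndarray:
        """Per-population MSD (Å²) at the given temperatures; shape (npop, nT)."""
        T = np.atleast_1d(np.asarray(temperature, dtype=float))
        return np.array(
            [
                p.u2_ref + (TWO_KB_A2_PER_K / p.k_prime) * (T - self.t_ref)
                for p in self.populations
            ]
        )

    def elastic_form(self, q, temperature) -> np.ndarray:
        """Mixture elastic form factor Σ_p w_p·exp(-Q²·u²_p(T)/6); (nq, nT)."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        u2 = self.u2(temperature)  # (npop, nT)
        w = np.array([p.weight for p in self.populations])
        return np.einsum(
            "p,pqt->qt", w, np.exp(-np.multiply.outer(u2, q**2) / 6.0).transpose(0, 2, 1)
        )

    def background_on(self, q) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.background, dtype=float), np.shape(q)
        ).astype(float)


@dataclass
class RawScanBundle:
    """The measurement triplet the reduction consumes, plus generative truth."""

    sample: ElasticScanSet
    empty_cell: ElasticScanSet
    vanadium: ElasticScanSet
    truth: DynamicsModel
    seed: int
    instrument: InstrumentConfig | None = None

    def __post_init__(self):
        for scan in (self.empty_cell, self.vanadium):
            if not np.array_equal(scan.q, self.sample.q):
                raise ValueError("all three scans must share the q grid")
        if not np.array_equal(self.empty_cell.temperature, self.sample.temperature):
            raise ValueError("sample and empty-cell scans must share temperatures")
        if self.vanadium.temperature.size != 1:
            raise ValueError("vanadium scan must have exactly one temperature")


@dataclass
class KillCurveParams:
    """Two-subpopulation death model parameters (rates in day⁻¹)."""

    n0: float = 1.0
    f_sensitive: float = 0.99
    k_fast: float = 2.0
    k_slow: float = 0.05
    noise_cv: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.f_sensitive <= 1.0:
            raise ValueError("f_sensitive must be in [0, 1]")
        if not self.k_fast >= self.k_slow >= 0.0:
            raise ValueError("need k_fast >= k_slow >= 0")
        if not self.n0 > 0:
            raise ValueError("n0 must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    def expectation(self, t_days) -> np.ndarray:
        t = np.asarray(t_days, dtype=float)
        return self.n0 * (
            self.f_sensitive * np.exp(-self.k_fast * t)
            + (1.0 - self.f_sensitive) * np.exp(-self.k_slow * t)
        )


@dataclass(frozen=True)
class MixtureComponent:
    """One bivariate log-normal cytometry component (means/sds in log10 a.u.)."""

    weight: float
    mean_syto: float
    mean_pi: float
    sd_syto: float
    sd_pi: float

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if not (self.sd_syto > 0 and self.sd_pi > 0):
            raise ValueError("sds must be positive")


@dataclass
class CytometryMixture:
    """Mixture of log-normal (SYTO9, PI) populations with an event budget."""

    components: list
    n_events: int = 10_000

    def __post_init__(self):
        self.components = [
            c if isinstance(c, MixtureComponent) else MixtureComponent(*c)
            for c in self.components
        ]
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1 (got {w!r})")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_elastic_bundle(
    model: DynamicsModel,
    instrument: InstrumentConfig | None = None,
    seed: int = 0,
    noise: bool = True,
) -> RawScanBundle:
    """Simulate the sample / empty-cell / vanadium scan triplet.

    Expected sample counts at (Q, T) are
    transmission·[amplitude·Σ_p w_p·exp(-Q²·u²_p(T)/6) + background(Q)]
    ·efficiency(Q)·(monitor/1e6); the empty-cell run records the background
    alone (no sample in the beam, so no transmission factor) and the
    vanadium run is Q-flat before detector efficiency.  With ``noise`` on,
    counts are Poisson draws; errors are sqrt(counts) either way (sqrt of
    the expectation when noise is off).
    """
    instrument = instrument or InstrumentConfig()
    q = instrument.q_grid
    T = instrument.temperatures
    eff = instrument.efficiency
    mon_scale = instrument.monitor / REFERENCE_MONITOR
    form = model.elastic_form(q, T)  # (nq, nT)
    bg = model.background_on(q)[:, None]
    sample_mean = (
        instrument.transmission * (model.amplitude * form + bg) * eff[:, None] * mon_scale
    )
    empty_mean = np.broadcast_to(bg * eff[:, None] * mon_scale, sample_mean.shape).copy()
    van_T = np.array([298.0])
    van_mean = (model.amplitude * eff * mon_scale)[:, None]
    rng = np.random.default_rng(seed)
    if noise:
        sample_counts = rng.poisson(sample_mean).astype(float)
        empty_counts = rng.poisson(empty_mean).astype(float)
        van_counts = rng.poisson(van_mean).astype(float)
    else:
        sample_counts, empty_counts, van_counts = sample_mean, empty_mean, van_mean

    def _scan(run_type, temps, counts):
        return ElasticScanSet(
            run_type=run_type,
            q=q.copy(),
            temperature=temps,
            counts=counts,
            count_err=np.sqrt(np.clip(counts, 1.0, None)),
            monitor=instrument.monitor,
        )

    return RawScanBundle(
        sample=_scan("sample", T.copy(), sample_counts),
        empty_cell=_scan("empty_cell", T.copy(), empty_counts),
        vanadium=_scan("vanadium", van_T, van_counts),
        truth=model,
        seed=int(seed),
        instrument=instrument,
    )


def simulate_kill_curve(
    params: KillCurveParams,
    times,
    seed: int = 0,
    noise: bool = True,
) -> GrowthCurve:
    """Two-phase death curve sampled at ``times`` (days).

    The noise-free expectation is
    n(t) = n0·[f·exp(-k_fast·t) + (1-f)·exp(-k_slow·t)]; noise is
    mean-preserving multiplicative log-normal with coefficient of variation
    ``params.noise_cv``.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    n = params.expectation(t)
    if noise and params.noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(params.noise_cv**2))
        n = n * np.exp(rng.normal(0.0, sigma, size=t.shape) - 0.5 * sigma**2)
    return GrowthCurve(
        time=t,
        density=n,
        time_unit="d",
        condition={"kind": "kill_curve"},
    )


def simulate_recovery_curve(
    lag: float,
    growth_rate: float,
    od0: float,
    times,
    noise_cv: float = 0.0,
    seed: int = 0,
    carrying: float | None = None,
) -> GrowthCurve:
    """Regrowth curve: flat at ``od0`` until ``lag`` (days), then exponential.

    ``growth_rate`` is per hour and ``times`` are hours.  The expectation is
    od0 for t < lag and od0·exp(rate·(t - lag)) afterwards, optionally
    capped at ``carrying``; noise is multiplicative log-normal.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if growth_rate < 0:
        raise ValueError("growth_rate must be non-negative")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    lag_h = lag * 24.0
    od = od0 * np.exp(growth_rate * np.clip(t - lag_h, 0.0, None))
    if carrying is not None:
        od = np.minimum(od, carrying)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        od = od * np.exp(rng.normal(0.0, sigma, size=t.shape) - 0.5 * sigma**2)
    return GrowthCurve(
        time=t,
        density=od,
        time_unit="h",
        condition={"kind": "recovery", "lag_days": lag},
    )


def simulate_cytometry_events(mixture: CytometryMixture, seed: int = 0) -> EventTable:
    """Draw (SYTO9, PI) event pairs from a log-normal mixture.

    Channels are 10**N(mean, sd) per component (independent channels);
    the component index is retained in ``truth_label``.
    """
    rng = np.random.default_rng(seed)
    n = mixture.n_events
    w = np.array([c.weight for c in mixture.components])
    labels = rng.choice(len(w), size=n, p=w / w.sum())
    mean_s = np.array([c.mean_syto for c in mixture.components])[labels]
    mean_p = np.array([c.mean_pi for c in mixture.components])[labels]
    sd_s = np.array([c.sd_syto for c in mixture.components])[labels]
    sd_p = np.array([c.sd_pi for c in mixture.components])[labels]
    syto = 10.0 ** rng.normal(mean_s, sd_s)
    pi = 10.0 ** rng.normal(mean_p, sd_p)
    return EventTable(syto9=syto, pi=pi, truth_label=labels)


def simulate_oxygen_trace(
    rate: float,
    o2_0: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 0.5,
    cell_count: float = 2.0e8,
    volume: float = 0.005,
) -> OxygenTrace:
    """Linear oxygen-depletion trace O₂(t) = max(o2_0 - rate·t, 0) + noise.

    ``rate`` is in µmol·L⁻¹·min⁻¹, ``duration`` in minutes sampled every
    ``dt`` minutes; Gaussian sensor noise with sd ``noise_sd`` is clipped at
    zero (dissolved oxygen cannot be negative).
    """
    if not o2_0 > 0:
        raise ValueError("o2_0 must be positive")
    if not duration > 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(0.0, duration + 1e-9, dt)
    o2 = np.clip(o2_0 - rate * t, 0.0, None)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        o2 = np.clip(o2 + rng.normal(0.0, noise_sd, size=t.shape), 0.0, None)
    return OxygenTrace(time=t, o2=o2, cell_count=cell_count, volume=volume)
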