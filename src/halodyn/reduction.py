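"""Reduction of elastic neutron scans: empty-cell subtraction and vanadium
normalization with analytic error propagation.

An elastic scan records, for each momentum transfer Q and temperature T, the
neutron counts integrated over the instrument's elastic energy window.  Three
runs make up a measurement: the sample run, an empty-cell run (the sample
holder alone) and a vanadium run (a purely incoherent elastic scatterer used
to calibrate detector efficiency and geometry).  Reduction produces the
normalized elastic intensity

    I(Q, T) = [sample(Q, T) - transmission · empty(Q, T)] / vanadium(Q)

with every run first divided by its beam-monitor count so that runs of
different durations are commensurable.  Counting errors are propagated in
quadrature; channels with non-positive vanadium counts are masked rather than
producing infinities, and negative post-subtraction intensities are retained
(clipping would bias downstream weighted fits) but counted in the provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElasticScanSet",
    "ReducedScan",
    "subtract_empty_cell",
    "normalize_vanadium",
    "reduce_bundle",
]

_RUN_TYPES = ("sample", "empty_cell", "vanadium")


@dataclass
class ElasticScanSet:
    """Raw (or partially corrected) elastic counts on a (Q, T) grid.

    Parameters
    ----------
    run_type : {"sample", "empty_cell", "vanadium"}
    q : ndarray, shape (nq,)
        Momentum transfer values, Å⁻¹, strictly increasing.
    temperature : ndarray, shape (nt,)
        Scan temperatures in K, strictly increasing.
    counts : ndarray, shape (nq, nt)
        Detector counts per (Q, T) channel.  May be negative after
        empty-cell subtraction.
    count_err : ndarray, shape (nq, nt), optional
        One-sigma counting error; defaults to sqrt(max(counts, 0)).
    monitor : float
        Incident-beam monitor count used for normalization.
    provenance : list of str
        Reduction steps already applied to these counts.
    """

    run_type: str
    q: np.ndarray
    temperature: np.ndarray
    counts: np.ndarray
    count_err: np.ndarray | None = None
    monitor: float = 1.0
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.temperature = np.atleast_1d(np.asarray(self.temperature, dtype=float))
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        if self.run_type not in _RUN_TYPES:
            raise ValueError(f"run_type must be one of {_RUN_TYPES}, got {self.run_type!r}")
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a non-empty 1-d array")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if self.counts.shape != (self.q.size, self.temperature.size):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"(|q|, |temperature|) = ({self.q.size}, {self.temperature.size})"
            )
        if not self.monitor > 0:
            raise ValueError("monitor must be positive")
        if self.count_err is None:
            self.count_err = np.sqrt(np.clip(self.counts, 0.0, None))
        else:
            self.count_err = np.asarray(self.count_err, dtype=float)
            if self.count_err.ndim == 1:
                self.count_err = self.count_err[:, None]
            if self.count_err.shape != self.counts.shape:
                raise ValueError("count_err shape does not match counts")
            if np.any(self.count_err < 0):
                raise ValueError("count_err must be non-negative")

    @property
    def n_q(self) -> int:
        return self.q.size

    @property
    def n_temperature(self) -> int:
        return self.temperature.size

    def monitor_scaled(self) -> "ElasticScanSet":
        """Return a copy with counts divided by the monitor (monitor -> 1)."""
        return ElasticScanSet(
            run_type=self.run_type,
            q=self.q.copy(),
            temperature=self.temperature.copy(),
            counts=self.counts / self.monitor,
            count_err=self.count_err / self.monitor,
            monitor=1.0,
            provenance=self.provenance + [f"monitor_scaled(monitor={self.monitor:g})"],
        )


@dataclass
class ReducedScan:
    """Background-subtracted, vanadium-normalized elastic intensities.

    ``mask`` is True for usable channels; masked-out channels may hold
    non-finite intensities.  ``provenance`` records every reduction step
    with its parameters.
    """

    q: np.ndarray
    temperature: np.ndarray
    intensity: np.ndarray
    intensity_err: np.ndarray
    mask: np.ndarray
    provenance: list = field(default_factory=list)
    q_unit: str = "invA"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.temperature = np.atleast_1d(np.asarray(self.temperature, dtype=float))
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.intensity_err = np.asarray(self.intensity_err, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (self.q.size, self.temperature.size)
        for name in ("intensity", "intensity_err", "mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match (|q|, |temperature|)")
        if np.any(self.intensity_err[self.mask] < 0):
            raise ValueError("unmasked intensity_err must be non-negative")
        if not self.provenance:
            raise ValueError("provenance must be non-empty for a reduced scan")

    @property
    def n_q(self) -> int:
        return self.q.size

    @property
    def n_temperature(self) -> int:
        return self.temperature.size


def subtract_empty_cell(
    sample: ElasticScanSet,
    empty: ElasticScanSet,
    transmission: float = 0.90,
) -> ElasticScanSet:
    """Subtract the transmission-scaled empty-cell counts from the sample.

    Both runs are monitor-normalized first; errors combine in quadrature.
    An empty-cell run with a single temperature is broadcast to all sample
    temperatures.  Negative corrected counts are retained, not clipped, and
    their number is recorded in the provenance.

    The default transmission of 0.90 reflects the thin flat-cell geometry
    typical of in-vivo elastic scans (sample transmission around 90%,
    chosen to make multiple scattering negligible).
    """
    if not 0.0 < transmission <= 1.0:
        raise ValueError(f"transmission must be in (0, 1], got {transmission}")
    if not np.array_equal(sample.q, empty.q):
        raise ValueError("sample and empty-cell scans have mismatched q grids")
    s = sample.monitor_scaled()
    e = empty.monitor_scaled()
    if e.n_temperature == 1:
        e_counts = np.broadcast_to(e.counts, s.counts.shape)
        e_err = np.broadcast_to(e.count_err, s.counts.shape)
    elif np.array_equal(e.temperature, s.temperature):
        e_counts, e_err = e.counts, e.count_err
    else:
        raise ValueError(
            "empty-cell temperatures must match the sample's or be a single scan"
        )
    corrected = s.counts - transmission * e_counts
    err = np.sqrt(s.count_err**2 + transmission**2 * e_err**2)
    n_negative = int(np.sum(corrected < 0))
    return ElasticScanSet(
        run_type="sample",
        q=s.q,
        temperature=s.temperature,
        counts=corrected,
        count_err=err,
        monitor=1.0,
        provenance=s.provenance
        + [
            f"subtract_empty_cell(transmission={transmission:g},"
            f" n_negative={n_negative})"
        ],
    )


def normalize_vanadium(
    corrected: ElasticScanSet, vanadium: ElasticScanSet
) -> ReducedScan:
    """Normalize corrected counts by a single-temperature vanadium scan.

    The vanadium run calibrates detector efficiency: I(Q,T) =
    corrected(Q,T)/vanadium(Q) after monitor scaling, with relative errors
    added in quadrature.  Channels whose vanadium counts are non-positive
    are masked for every temperature.
    """
    if not np.array_equal(corrected.q, vanadium.q):
        raise ValueError("corrected and vanadium scans have mismatched q grids")
    if vanadium.n_temperature != 1:
        raise ValueError("vanadium scan must have exactly one temperature")
    c = corrected.monitor_scaled()
    v = vanadium.monitor_scaled()
    v_counts = v.counts[:, 0]
    v_err = v.count_err[:, 0]
    good_v = v_counts > 0
    if not np.any(good_v):
        raise ValueError("all vanadium channels are non-positive; cannot normalize")
    mask = np.broadcast_to(good_v[:, None], c.counts.shape).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        intensity = np.where(mask, c.counts / v_counts[:, None], np.nan)
        rel_c = np.where(c.counts != 0, c.count_err / c.counts, 0.0)
        rel_v = np.where(good_v, v_err / np.where(good_v, v_counts, 1.0), 0.0)
        err = np.where(
            mask,
            np.abs(intensity) * np.sqrt(rel_c**2 + rel_v[:, None] ** 2),
            np.nan,
        )
        # channels with exactly zero corrected counts: propagate the absolute error
        zero_c = mask & (c.counts == 0)
        err[zero_c] = (c.count_err / v_counts[:, None])[zero_c]
    n_masked = int(np.sum(~good_v))
    return ReducedScan(
        q=c.q,
        temperature=c.temperature,
        intensity=intensity,
        intensity_err=err,
        mask=mask,
        provenance=c.provenance + [f"normalize_vanadium(n_masked_q={n_masked})"],
    )


def reduce_bundle(bundle, transmission: float | None = None) -> ReducedScan:
    """Full reduction of a raw scan triplet: empty-cell subtraction followed
    by vanadium normalization.

    ``transmission`` defaults to the instrument transmission recorded in the
    bundle (0.90 if the bundle carries none).
    """
    if transmission is None:
        instrument = getattr(bundle, "instrument", None)
        transmission = getattr(instrument, "transmission", 0.90)
    corrected = subtract_empty_cell(bundle.sample, bundle.empty_cell, transmission)
    return normalize_vanadium(corrected, bundle.vanadium)
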