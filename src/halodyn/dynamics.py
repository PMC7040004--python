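"""Proteome molecular-dynamics observables from reduced elastic scans.

In the Gaussian approximation the normalized elastic intensity of an
incoherent scatterer falls off as

    I(Q, T) ∝ exp(-Q² ⟨u²(T)⟩ / 6)

so a weighted straight-line fit of ln I against Q² over a low-Q window
yields the mean square displacement ⟨u²⟩ (Å²) at each temperature (the /6
divisor is the full-amplitude convention of the resilience literature).
For a proteome in a quasi-harmonic mean potential ⟨u²⟩ grows linearly with
temperature and the mean effective force constant — the structural
resilience — follows from the slope:

    ⟨k'⟩ = 2 k_B / (d⟨u²⟩/dT)   [N/m, with ⟨u²⟩ in Å²: 0.0027613/slope]

Softer, partially unfolded ensembles have larger MSD slopes and hence lower
⟨k'⟩.  The Gaussian approximation holds for Q²⟨u²⟩/6 ≲ 2; points beyond the
validity limit are trimmed from the high-Q side before refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import K_B, TWO_KB_A2_PER_K  # noqa: F401  (K_B re-exported)
from .reduction import ReducedScan, reduce_bundle

__all__ = [
    "MSDSeries",
    "ForceConstant",
    "ForceConstantModel",
    "ResilienceModel",
    "ResilienceResults",
    "fit_msd_series",
    "fit_force_constant",
    "observable_length_scale",
]


def observable_length_scale(q: float) -> float:
    """Real-space length scale (Å) probed at momentum transfer ``q`` (Å⁻¹).

    A scattering vector of modulus Q is sensitive to motions with
    amplitudes around 2π/Q.
    """
    if not q > 0:
        raise ValueError("q must be positive")
    return 2.0 * math.pi / q


# ---------------------------------------------------------------------------
# MSD extraction
# ---------------------------------------------------------------------------


@dataclass
class MSDSeries:
    """Per-temperature mean square displacements from Gaussian fits.

    Only temperatures whose fit succeeded are kept; ``failed_temperatures``
    lists the ones dropped for having too few usable Q points.
    """

    temperature: np.ndarray  # K
    u2: np.ndarray  # Å²
    u2_err: np.ndarray  # Å²
    q_window: np.ndarray  # (nT, 2) Å⁻¹ actually used
    n_points: np.ndarray
    fit_r2: np.ndarray
    n_dropped_nonpositive: np.ndarray
    failed_temperatures: np.ndarray
    normalize_to_reference: bool = False

    def __len__(self) -> int:
        return self.temperature.size

    def summary(self) -> str:
        lines = [
            "MSD series (Gaussian-approximation fits of ln I vs Q²)",
            "======================================================",
            f"{'T (K)':>8} {'u2 (A^2)':>10} {'err':>8} {'Q window':>14} {'npts':>5} {'R2':>7}",
        ]
        for i in range(len(self)):
            lines.append(
                f"{self.temperature[i]:8.1f} {self.u2[i]:10.4f} {self.u2_err[i]:8.4f} "
                f"[{self.q_window[i, 0]:.2f}, {self.q_window[i, 1]:.2f}] "
                f"{int(self.n_points[i]):5d} {self.fit_r2[i]:7.4f}"
            )
        if self.failed_temperatures.size:
            lines.append(f"failed temperatures: {self.failed_temperatures.tolist()}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Quick-look errorbar plot of ⟨u²⟩ versus temperature."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.temperature, self.u2, yerr=self.u2_err, fmt="o", capsize=3)
        ax.set_xlabel("temperature (K)")
        ax.set_ylabel(r"$\langle u^2\rangle$ ($\mathrm{\AA}^2$)")
        return ax


def _wls_line(x, y, w):
    """Weighted least-squares line fit; returns slope, intercept, their
    variances (known-weights convention: Var ∝ 1/Σw) and weighted R²."""
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    var_slope = 1.0 / sxx
    var_intercept = 1.0 / sw + xbar**2 / sxx
    resid = y - intercept - slope * x
    rss = (w * resid**2).sum()
    tss = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return slope, intercept, var_slope, var_intercept, r2


def fit_msd_series(
    reduced: ReducedScan,
    q_window: tuple = (0.3, 1.5),
    q_unit: str = "invA",
    normalize_to_reference: bool = False,
    min_points: int = 4,
    validity_limit: float = 2.0,
) -> MSDSeries:
    """Extract ⟨u²⟩(T) by weighted Gaussian fits on a low-Q window.

    For each temperature, ln I is regressed on Q² with weights (I/σ_I)²
    (the inverse variance of ln I) and u² = -6·slope.  The Gaussian-validity
    criterion q_max²·u²/6 <= ``validity_limit`` is enforced by repeatedly
    dropping the highest-Q point and refitting while more than
    ``min_points`` remain.  Non-positive intensities inside the window are
    dropped and counted.

    ``q_unit`` may be ``"invA"`` (default) or ``"invnm"``; with the latter
    both the scan's Q values and ``q_window`` are interpreted in nm⁻¹ and
    converted internally, leaving all outputs in Å units.
    """
    if q_unit == "invA":
        q = reduced.q
        win = q_window
    elif q_unit == "invnm":
        q = reduced.q / 10.0
        win = (q_window[0] / 10.0, q_window[1] / 10.0)
    else:
        raise ValueError("q_unit must be 'invA' or 'invnm'")
    q_lo, q_hi = win
    intensity = reduced.intensity
    err = reduced.intensity_err
    if normalize_to_reference:
        ref = intensity[:, 0]
        ref_err = err[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.sqrt(
                (err / np.where(intensity != 0, intensity, np.nan)) ** 2
                + (ref_err / np.where(ref != 0, ref, np.nan))[:, None] ** 2
            )
            intensity = intensity / ref[:, None]
            err = np.abs(intensity) * rel

    temps, u2s, u2errs, wins, npts, r2s, ndrops = [], [], [], [], [], [], []
    failed = []
    in_window = (q >= q_lo) & (q <= q_hi)
    for j, T in enumerate(reduced.temperature):
        usable = in_window & reduced.mask[:, j] & np.isfinite(intensity[:, j])
        positive = usable & (intensity[:, j] > 0)
        n_nonpos = int(np.sum(usable) - np.sum(positive))
        idx = np.flatnonzero(positive)
        if idx.size < min_points:
            failed.append(T)
            continue
        qq = q[idx]
        ii = intensity[idx, j]
        ee = err[idx, j]
        # trimming loop: enforce the Gaussian validity limit at the window top
        while True:
            x = qq**2
            y = np.log(ii)
            sig = ee / ii  # sd of ln I
            w = 1.0 / np.where(sig > 0, sig, np.min(sig[sig > 0]) if np.any(sig > 0) else 1.0) ** 2
            slope, intercept, var_slope, _, r2 = _wls_line(x, y, w)
            u2 = -6.0 * slope
            if qq[-1] ** 2 * u2 / 6.0 > validity_limit and qq.size > min_points:
                qq, ii, ee = qq[:-1], ii[:-1], ee[:-1]
                continue
            break
        temps.append(T)
        u2s.append(u2)
        u2errs.append(6.0 * math.sqrt(var_slope))
        wins.append((qq[0], qq[-1]))
        npts.append(qq.size)
        r2s.append(r2)
        ndrops.append(n_nonpos)
    if not temps:
        raise ValueError("MSD fit failed at every temperature")
    return MSDSeries(
        temperature=np.array(temps),
        u2=np.array(u2s),
        u2_err=np.array(u2errs),
        q_window=np.array(wins),
        n_points=np.array(npts),
        fit_r2=np.array(r2s),
        n_dropped_nonpositive=np.array(ndrops),
        failed_temperatures=np.array(failed),
        normalize_to_reference=normalize_to_reference,
    )


# ---------------------------------------------------------------------------
# force constant
# ---------------------------------------------------------------------------


@dataclass
class ForceConstant:
    """Mean effective force constant ⟨k'⟩ from the MSD temperature slope.

    ``k_prime`` is NaN when the fitted slope is non-positive (the
    ``non_positive_slope`` flag is set instead of raising).
    """

    k_prime: float  # N/m
    k_prime_err: float
    slope: float  # Å²/K
    slope_err: float
    intercept: float  # Å² at T = 0 of the regression frame
    method: str
    n_boot: int
    flags: list = field(default_factory=list)
    n_temperatures: int = 0

    @property
    def defined(self) -> bool:
        return "non_positive_slope" not in self.flags

    def conf_int(self, z: float = 1.96) -> tuple:
        """Normal-theory confidence interval for ⟨k'⟩."""
        if not self.defined:
            return (float("nan"), float("nan"))
        return (self.k_prime - z * self.k_prime_err, self.k_prime + z * self.k_prime_err)

    def consistent_with(self, other: "ForceConstant", z: float = 1.96) -> bool:
        """Whether two measured force constants are statistically
        indistinguishable at level z, using the SE of their difference."""
        if not (self.defined and other.defined):
            return False
        se = math.sqrt(self.k_prime_err**2 + other.k_prime_err**2)
        return abs(self.k_prime - other.k_prime) <= z * se

    def summary(self) -> str:
        kp = f"{self.k_prime:.4f} ± {self.k_prime_err:.4f} N/m" if self.defined else "undefined"
        return "\n".join(
            [
                "Effective force constant <k'>",
                "=============================",
                f"k'                 : {kp}",
                f"d<u2>/dT (A^2/K)   : {self.slope:.6g} ± {self.slope_err:.2g}",
                f"temperatures used  : {self.n_temperatures}",
                f"error method       : {self.method} (n_boot={self.n_boot})",
                f"flags              : {', '.join(self.flags) or 'none'}",
            ]
        )


class ForceConstantModel:
    """Weighted linear model ⟨u²⟩(T) = a + b·T fitted to an MSD series.

    ``fit`` supports analytic error propagation (default) or a
    temperature-resampling bootstrap; ⟨k'⟩ = 2k_B/b with the Å²→m²
    conversion folded into the constant.
    """

    def __init__(self, series: MSDSeries):
        ok = np.isfinite(series.u2) & np.isfinite(series.u2_err)
        if np.sum(ok) < 3:
            raise ValueError("force-constant fit needs >= 3 temperatures")
        self.T = series.temperature[ok]
        self.u2 = series.u2[ok]
        self.u2_err = series.u2_err[ok]

    def _weights(self):
        err = self.u2_err.copy()
        pos = err > 0
        if not np.any(pos):
            return np.ones_like(err)
        err[~pos] = err[pos].min()
        return 1.0 / err**2

    def fit(
        self,
        method: str = "analytic_propagation",
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> ForceConstant:
        if method not in ("analytic_propagation", "bootstrap"):
            raise ValueError("method must be 'analytic_propagation' or 'bootstrap'")
        if method == "bootstrap" and seed is None:
            raise ValueError("bootstrap error estimation requires a seed")
        w = self._weights()
        slope, intercept, var_slope, _, _ = _wls_line(self.T, self.u2, w)
        slope_err = math.sqrt(var_slope)
        flags = []
        if slope <= 0:
            flags.append("non_positive_slope")
            k = k_err = float("nan")
        else:
            k = TWO_KB_A2_PER_K / slope
            if method == "analytic_propagation":
                k_err = k * slope_err / slope
            else:
                rng = np.random.default_rng(seed)
                n = self.T.size
                ks = []
                for _ in range(n_boot):
                    idx = rng.integers(0, n, size=n)
                    if np.unique(self.T[idx]).size < 2:
                        continue
                    b, *_ = _wls_line(self.T[idx], self.u2[idx], w[idx])
                    if b > 0:
                        ks.append(TWO_KB_A2_PER_K / b)
                k_err = float(np.std(ks, ddof=1)) if len(ks) > 1 else float("nan")
        return ForceConstant(
            k_prime=float(k),
            k_prime_err=float(k_err),
            slope=float(slope),
            slope_err=float(slope_err),
            intercept=float(intercept),
            method=method,
            n_boot=n_boot if method == "bootstrap" else 0,
            flags=flags,
            n_temperatures=int(self.T.size),
        )


def fit_force_constant(
    series: MSDSeries,
    method: str = "analytic_propagation",
    n_boot: int = 1000,
    seed: int | None = None,
) -> ForceConstant:
    """Estimate ⟨k'⟩ (N/m) from the MSD temperature slope; see
    ForceConstantModel."""
    return ForceConstantModel(series).fit(method=method, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# end-to-end convenience model
# ---------------------------------------------------------------------------


@dataclass
class ResilienceResults:
    """Joint results of the MSD extraction and force-constant fit."""

    reduced: ReducedScan
    msd: MSDSeries
    force: ForceConstant

    def summary(self) -> str:
        return self.msd.summary() + "\n\n" + self.force.summary()

    def plot(self, ax=None):
        ax = self.msd.plot(ax=ax)
        if self.force.defined:
            T = self.msd.temperature
            ax.plot(
                T,
                self.force.intercept + self.force.slope * T,
                "-",
                label=f"k' = {self.force.k_prime:.3f} N/m",
            )
            ax.legend()
        return ax


class ResilienceModel:
    """Full elastic-scan analysis: reduction → MSD series → ⟨k'⟩.

    Construct from a ReducedScan, or from a raw scan bundle with
    ``from_bundle`` (which performs the reduction first).
    """

    def __init__(
        self,
        reduced: ReducedScan,
        q_window: tuple = (0.3, 1.5),
        q_unit: str = "invA",
        normalize_to_reference: bool = False,
    ):
        self.reduced = reduced
        self.q_window = q_window
        self.q_unit = q_unit
        self.normalize_to_reference = normalize_to_reference

    @classmethod
    def from_bundle(cls, bundle, transmission: float | None = None, **kwargs):
        return cls(reduce_bundle(bundle, transmission=transmission), **kwargs)

    def _fit_msd(self) -> MSDSeries:
        return fit_msd_series(
            self.reduced,
            q_window=self.q_window,
            q_unit=self.q_unit,
            normalize_to_reference=self.normalize_to_reference,
        )

    def fit(
        self,
        method: str = "analytic_propagation",
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> ResilienceResults:
        msd = self._fit_msd()
        force = fit_force_constant(msd, method=method, n_boot=n_boot, seed=seed)
        return ResilienceResults(reduced=self.reduced, msd=msd, force=force)
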