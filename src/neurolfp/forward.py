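"""Source-to-potential forward schemas.

Three schemas map per-compartment transmembrane currents to extracellular
potential under the quasistatic, purely-ohmic volume-conductor assumption:

* **PSA** (point-source approximation): each compartment's current emanates
  from a point at the neurite centre, ``phi = I / (4 pi sigma r)``.
* **LSA** (line-source approximation): the current is distributed uniformly
  along the compartment axis; integrating the point-source kernel along the
  segment gives the closed form
  ``phi = I/(4 pi sigma ds) * ln[(sqrt(h^2+r^2)-h) / (sqrt(l^2+r^2)-l)]``
  with ``(r, h, l)`` the cylindrical electrode coordinates of
  :func:`neurolfp.core.line_coordinates`.
* **RC**: the medium's low-pass property modeled as a first-order
  resistance-capacitance filter applied to each source current, combined
  with the PSA geometric factor so the output remains a distance-dependent
  voltage. (A literal distance-free summation of filtered currents is
  available via ``rc_literal=True``.)

Unit bookkeeping: with currents in nA, distances in um and sigma in S/m,
``I/(4 pi sigma r)`` is in mV, hence the single factor of 1e3 to uV.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, signal

from .core import (
    ConfigurationError,
    ConvergenceError,
    DataError,
    ElectrodeArray,
    GeometryError,
    LFPTrace,
    Medium,
    Point3,
    SegmentSource,
    SourceSet,
)

METHODS = ("psa", "lsa", "rc")

_UV_PER_NA_UM = 1.0e3  # nA / (S/m * um) -> uV


def _check_method(method: str) -> str:
    m = method.lower()
    if m not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; expected one of {METHODS}")
    return m


def psa_potential(current, distance, medium: Medium):
    """Point-source potential in uV for a current (nA) at a distance (um).

    Distances are clamped from below to ``medium.min_distance``.
    Accepts scalars or broadcastable arrays.
    """
    current = np.asarray(current, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if not (np.all(np.isfinite(current)) and np.all(np.isfinite(distance))):
        raise DataError("non-finite current or distance")
    r = np.maximum(distance, medium.min_distance)
    out = _UV_PER_NA_UM * current / (4.0 * np.pi * medium.sigma * r)
    return out if out.ndim else float(out)


def _sqrt_minus(v, r):
    """sqrt(v^2 + r^2) - v, evaluated without cancellation for v >> r > 0."""
    v = np.asarray(v, dtype=float)
    r = np.asarray(r, dtype=float)
    s = np.hypot(v, r)
    safe = np.where(v > 0, s + v, 1.0)
    return np.where(v > 0, r * r / safe, s - v)


def lsa_log_factor(r, h, l):
    """ln[(sqrt(h^2+r^2)-h)/(sqrt(l^2+r^2)-l)], stable at far field.

    Strictly positive arguments for r > 0 and any sign of h (l = ds + h > h).
    """
    return np.log(_sqrt_minus(h, r) / _sqrt_minus(l, r))


def _clamp_radial(r: float, segment: SegmentSource, medium: Medium) -> float:
    return max(r, medium.min_distance, segment.radius)


def lsa_potential(current: float, segment: SegmentSource, electrode, medium: Medium) -> float:
    """Line-source potential in uV of one segment at one electrode.

    The radial distance is clamped to at least ``max(medium.min_distance,
    segment.radius)``, since the line-source kernel is only meaningful
    outside the neurite. Raises GeometryError for a zero-length segment
    (use :func:`psa_potential` for spherical soma sources).
    """
    from .core import line_coordinates

    r, h, l = line_coordinates(segment, electrode)
    r = _clamp_radial(r, segment, medium)
    ds = segment.length
    value = (
        _UV_PER_NA_UM
        * current
        / (4.0 * np.pi * medium.sigma * ds)
        * lsa_log_factor(r, h, l)
    )
    return float(value)


def lsa_quadrature(
    current: float,
    segment: SegmentSource,
    electrode,
    medium: Medium,
    tol: float = 1e-10,
) -> float:
    """Line-source potential by adaptive quadrature of the integral form.

    Integrates ``I / (ds * 4 pi sigma * sqrt(r^2 + (h - s)^2))`` for
    ``s`` in ``[-ds, 0]``. This is the independent oracle for
    :func:`lsa_potential`; it shares only the coordinate computation.
    """
    from .core import line_coordinates

    r, h, _ = line_coordinates(segment, electrode)
    r = _clamp_radial(r, segment, medium)
    ds = segment.length

    def integrand(s):
        return 1.0 / np.sqrt(r * r + (h - s) ** 2)

    val, err = integrate.quad(integrand, -ds, 0.0, epsabs=0.0, epsrel=tol, limit=200)
    if err > max(tol * abs(val), 1e-14):
        raise ConvergenceError(
            f"quadrature error {err:.3e} exceeds tolerance for segment {segment.id}"
        )
    return float(_UV_PER_NA_UM * current / (4.0 * np.pi * medium.sigma * ds) * val)


def rc_filter(trace, dt: float, tau: float) -> np.ndarray:
    """First-order low-pass filter along the last axis, DC gain exactly 1.

    Discrete update ``y[k] = a*x[k] + (1-a)*y[k-1]`` with ``a = dt/(tau+dt)``
    and ``y[-1] = x[0]`` (starts at rest on the first sample).
    """
    if not tau > 0:
        raise ConfigurationError(f"tau must be > 0, got {tau}")
    if not dt > 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    x = np.atleast_2d(np.asarray(trace, dtype=float))
    alpha = dt / (tau + dt)
    zi = (1.0 - alpha) * x[:, :1]
    y, _ = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], x, axis=-1, zi=zi)
    return y[0] if np.asarray(trace).ndim == 1 else y


def source_weights(
    sources: SourceSet, positions: np.ndarray, medium: Medium, method: str
) -> np.ndarray:
    """Geometric weight matrix W (uV per nA), shape (n_electrodes, n_sources).

    ``phi = W @ currents`` evaluates the chosen schema at every electrode.
    Spherical (zero-length) sources always use the point-source kernel.
    For ``rc`` the PSA geometry is returned (temporal filtering is applied
    to the currents separately).
    """
    method = _check_method(method)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n_e, n_s = positions.shape[0], sources.n_sources
    if n_s == 0:
        return np.zeros((n_e, 0))

    mids = sources.midpoints()
    radii = sources.radii()
    floor = np.maximum(medium.min_distance, radii)  # per-segment clamp, um
    four_pi_sigma = 4.0 * np.pi * medium.sigma

    diff = positions[:, None, :] - mids[None, :, :]
    r_point = np.linalg.norm(diff, axis=2)
    w_psa = _UV_PER_NA_UM / (four_pi_sigma * np.maximum(r_point, floor[None, :]))

    if method in ("psa", "rc"):
        return w_psa

    lengths = sources.lengths()
    linear = (lengths > 0) & ~sources.spherical_mask()
    w = w_psa.copy()
    if linear.any():
        a = sources.starts()[linear]
        u = (sources.ends()[linear] - a) / lengths[linear][:, None]
        d = positions[:, None, :] - a[None, :, :]
        l = np.einsum("esk,sk->es", d, u)
        h = l - lengths[linear][None, :]
        r_sq = np.maximum(np.einsum("esk,esk->es", d, d) - l * l, 0.0)
        r = np.maximum(np.sqrt(r_sq), floor[linear][None, :])
        w[:, linear] = (
            _UV_PER_NA_UM
            / (four_pi_sigma * lengths[linear][None, :])
            * lsa_log_factor(r, h, l)
        )
    return w


def compute_lfp(
    sources: SourceSet,
    electrodes: ElectrodeArray,
    medium: Medium,
    method: str = "lsa",
    rc_literal: bool = False,
) -> LFPTrace:
    """Superpose per-source potentials at every electrode and time step.

    For ``psa``/``lsa`` each source contributes its schema potential at
    every step. For ``rc`` every source current is low-pass filtered with
    ``medium.tau`` and scaled by the PSA geometric factor before summation;
    with ``rc_literal=True`` the filtered currents are summed without any
    geometric factor (the distance-free form, identical at all electrodes
    and reported on the nA scale).
    """
    method = _check_method(method)
    positions = electrodes.positions()
    time = sources.time if sources.n_steps else np.array([])
    if sources.n_sources == 0:
        return LFPTrace(time, np.zeros((len(electrodes), sources.n_steps)), electrodes.labels)

    currents = sources.currents
    if method == "rc":
        currents = rc_filter(currents, sources.dt, medium.tau)
        if rc_literal:
            total = currents.sum(axis=0)
            values = np.tile(total, (len(electrodes), 1))
            return LFPTrace(time, values, electrodes.labels)

    w = source_weights(sources, positions, medium, method)
    return LFPTrace(time, w @ currents, electrodes.labels)


def compute_mea(
    sources: SourceSet,
    array: ElectrodeArray,
    medium: Medium,
    method: str = "lsa",
    rc_literal: bool = False,
) -> LFPTrace:
    """Simulated multi-electrode-array recording: the LFP at every grid point.

    Identical to :func:`compute_lfp` evaluated at each electrode of the
    array, preserving the array's (row-major grid) ordering.
    """
    if len(array) < 1:
        raise ConfigurationError("electrode array must contain at least one electrode")
    return compute_lfp(sources, array, medium, method, rc_literal=rc_literal)
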