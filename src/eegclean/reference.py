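"""Spherical-spline interpolation of bad channels and re-referencing.

Interpolation follows the Perrin spherical-spline construction: the scalp
potential is modelled as a constant plus a sum of spline kernels

    g(cos gamma) = (1/4pi) sum_{n=1}^{N} (2n+1) / (n (n+1))**m P_n(cos gamma)

with Legendre expansion order ``N`` (default 7) and stiffness ``m``
(default 4), fitted to the good electrodes (ridge-regularised) and
evaluated at the bad electrode positions.

Re-referencing supports subtraction of the all-channel average, of a
channel-subset mean, and the reference electrode standardisation
technique (REST), which maps average-referenced data to an approximate
infinity reference through a forward head model: here a three-concentric-
sphere head (brain/skull/scalp, relative radii 0.87/0.92/1.0, skull
conductivity 0.0125 of brain/scalp) sampled by a spherical cloud of
radial dipoles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.special import lpmv

from .recording import Montage, Recording

#: three-sphere model: relative radii and conductivities (brain, skull, scalp)
HEAD_RADII = (0.87, 0.92, 1.0)
HEAD_CONDUCTIVITIES = (1.0, 0.0125, 1.0)
#: dipole shell radius (fraction of brain radius) for the REST source grid
DIPOLE_SHELL = 0.7
#: spherical-harmonic degrees summed in the forward series
N_HARMONICS = 60


@dataclass(frozen=True)
class SplineSpec:
    """Spherical-spline parameters: Legendre order, stiffness, ridge."""

    legendre_order: int = 7
    stiffness: int = 4
    regularization: float = 1e-5

    def __post_init__(self) -> None:
        if self.legendre_order < 1:
            raise ValueError("legendre_order must be >= 1")
        if self.regularization < 0:
            raise ValueError("regularization must be nonnegative")


def _g_kernel(cosang: np.ndarray, spec: SplineSpec) -> np.ndarray:
    n = np.arange(1, spec.legendre_order + 1)
    coef = np.zeros(spec.legendre_order + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1.0)) ** spec.stiffness
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coef) / (4 * np.pi)


def spline_interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    spec: SplineSpec | None = None,
) -> np.ndarray:
    """Matrix M such that ``v_bad = M @ v_good`` under the spline model.

    Positions are unit vectors, shapes (n_good, 3) and (n_bad, 3).
    """
    spec = spec or SplineSpec()
    ng = good_pos.shape[0]
    G = _g_kernel(good_pos @ good_pos.T, spec)
    Gb = _g_kernel(bad_pos @ good_pos.T, spec)
    # fit constant + spline weights with ridge; constraint sum(weights) = 0
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G + spec.regularization * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    solve = np.linalg.solve(A, np.vstack([np.eye(ng), np.zeros(ng)]).reshape(ng + 1, ng))
    # rows: weights (ng) then constant; v_bad = Gb @ w + c0
    W = solve[:ng]
    c0 = solve[ng]
    return Gb @ W + c0[np.newaxis, :]


def spline_interpolate(
    rec: Recording,
    bad: list[str],
    montage: Montage | None = None,
    spec: SplineSpec | None = None,
) -> Recording:
    """Replace ``bad`` channels with their spherical-spline estimate.

    Good channels are untouched. The interpolated labels are recorded in
    the stage history for the quality report. Requires positions for all
    channels and at least 4 good channels.
    """
    montage = montage or rec.montage
    if not bad:
        return rec.with_data(rec.data.copy(), "spline_interpolate: none")
    if montage is None:
        raise ValueError("interpolation requires a montage")
    unknown = [l for l in bad if l not in rec.labels]
    if unknown:
        raise KeyError(f"bad channels not in recording: {unknown}")
    good = [l for l in rec.labels if l not in bad]
    if len(good) < 4:
        raise RuntimeError("fewer than 4 good channels; interpolation refused")
    pos_good = montage.unit_positions(good)
    pos_bad = montage.unit_positions(bad)
    M = spline_interpolation_matrix(pos_good, pos_bad, spec)
    out = rec.data.copy()
    gidx = [rec.labels.index(l) for l in good]
    bidx = [rec.labels.index(l) for l in bad]
    out[bidx] = M @ out[gidx]
    return rec.with_data(out, f"spline_interpolate: {bad}")


# ---------------------------------------------------------------------------
# re-referencing
# ---------------------------------------------------------------------------

def _reinstate_online_reference(rec: Recording) -> Recording:
    """Add the (all-zero) online reference channel back if declared and
    missing from the data."""
    if rec.online_reference is None or rec.online_reference in rec.labels:
        return rec
    lab = rec.online_reference
    if rec.montage is not None and lab not in rec.montage:
        raise ValueError(f"online reference {lab!r} has no montage position")
    data = np.vstack([rec.data, np.zeros((1, rec.n_samples))])
    out = Recording(
        data=data,
        fs=rec.fs,
        labels=rec.labels + [lab],
        montage=rec.montage,
        online_reference=lab,
        history=rec.history + [f"reinstated online reference {lab}"],
        source=rec.source,
    )
    return out


def rereference(
    rec: Recording, mode: str, subset: list[str] | None = None
) -> Recording:
    """Re-reference to the channel average, a channel subset, or REST.

    If an online reference is declared, its all-zero trace is reinstated
    first so its signal is recovered by the subtraction.
    """
    if mode == "none":
        return rec
    if mode not in ("average", "subset", "REST"):
        raise ValueError(f"unknown re-reference mode {mode!r}")
    rec = _reinstate_online_reference(rec)
    if mode == "REST":
        return rest_rereference(rec)
    if mode == "average":
        ref = rec.data.mean(axis=0, keepdims=True)
        stage = "rereference: average"
    else:
        if not subset:
            raise ValueError("subset re-reference requires a non-empty subset")
        unknown = [l for l in subset if l not in rec.labels]
        if unknown:
            raise ValueError(f"subset channels not in recording: {unknown}")
        idx = [rec.labels.index(l) for l in subset]
        ref = rec.data[idx].mean(axis=0, keepdims=True)
        stage = f"rereference: subset {subset}"
    return rec.with_data(rec.data - ref, stage)


# ---------------------------------------------------------------------------
# REST: three-concentric-sphere forward model + infinity-reference estimator
# ---------------------------------------------------------------------------

def _shell_coefficients(n_max: int) -> np.ndarray:
    """Per-degree scalp-surface potential coefficients of the 3-shell model.

    For each spherical-harmonic degree n the radial solution in shell j is
    ``A_j r^n + B_j r^-(n+1)``; coefficients follow from continuity of the
    potential and of the radial current at each interface and zero current
    at the scalp surface, with the dipole's exterior expansion feeding the
    innermost shell. Returns ``c[n]`` such that the scalp potential from a
    unit source term is ``c[n] * (angular part)``; radii normalised to the
    scalp radius.
    """
    r1, r2, r3 = HEAD_RADII
    s1, s2, s3 = HEAD_CONDUCTIVITIES
    coefs = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3 ; B1 = 1 (source term)
        m = np.zeros((5, 5))
        rhs = np.zeros(5)
        # interface r1: potential continuity
        m[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0, 0]
        rhs[0] = -(r1 ** -(n + 1))
        # interface r1: radial current continuity
        m[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0,
            0,
        ]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # interface r2: potential continuity
        m[2] = [0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # interface r2: radial current continuity
        m[3] = [
            0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # scalp surface r3: zero radial current
        m[4] = [0, 0, 0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)]
        sol = np.linalg.solve(m, rhs)
        coefs[n] = sol[3] * r3**n + sol[4] * r3 ** -(n + 1)
    return coefs


def radial_dipole_grid(n_dipoles: int = 3000, seed: int = 0) -> np.ndarray:
    """Quasi-uniform unit directions for the radial dipole shell (Fibonacci
    sphere; ``seed`` rotates the grid)."""
    i = np.arange(n_dipoles) + 0.5
    phi = np.pi * (1 + 5**0.5) * i + seed
    z = 1 - 2 * i / n_dipoles
    r = np.sqrt(np.maximum(1 - z**2, 0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def leadfield_three_sphere(
    electrode_pos: np.ndarray, dipole_dirs: np.ndarray
) -> np.ndarray:
    """Scalp potentials (electrodes x dipoles) of unit radial dipoles.

    ``electrode_pos`` are unit vectors; dipoles sit at ``DIPOLE_SHELL *
    brain radius`` along ``dipole_dirs`` with radial moments. Potentials
    are referenced "at infinity" by construction of the series.
    """
    b = DIPOLE_SHELL * HEAD_RADII[0]
    coefs = _shell_coefficients(N_HARMONICS)
    cosang = np.clip(electrode_pos @ dipole_dirs.T, -1.0, 1.0)
    # radial dipole exterior expansion: source term n * b^(n-1) / (4 pi s1)
    n = np.arange(N_HARMONICS + 1)
    series = np.zeros(N_HARMONICS + 1)
    series[1:] = coefs[1:] * n[1:] * b ** (n[1:] - 1) / (4 * np.pi * HEAD_CONDUCTIVITIES[0])
    return npleg.legval(cosang, series)


def rest_rereference(
    rec: Recording,
    montage: Montage | None = None,
    n_dipoles: int = 3000,
) -> Recording:
    """Transform to the approximate infinity reference (REST).

    The average-referenced leadfield ``G_avg`` of the radial-dipole cloud
    is pseudo-inverted to recover equivalent sources from the
    average-referenced data, and the unreferenced leadfield ``G`` maps the
    sources back: ``V_inf = G pinv(G_avg) V_avg``. Because the data is
    average-referenced first, the result does not depend on the original
    reference choice.
    """
    montage = montage or rec.montage
    if montage is None:
        raise ValueError("REST requires a montage")
    rec = _reinstate_online_reference(rec)
    if rec.n_channels < 8:
        import warnings

        warnings.warn(
            "REST with fewer than 8 channels is poorly constrained",
            stacklevel=2,
        )
    pos = montage.unit_positions(rec.labels)
    G = leadfield_three_sphere(pos, radial_dipole_grid(n_dipoles))
    G_avg = G - G.mean(axis=0, keepdims=True)
    v_avg = rec.data - rec.data.mean(axis=0, keepdims=True)
    transform = G @ np.linalg.pinv(G_avg, rcond=1e-8)
    return rec.with_data(transform @ v_avg, f"rereference: REST ({n_dipoles} dipoles)")


# convenience: associated Legendre for tangential dipoles (used in tests
# and synthetic forward fields)
def lpmv1(n: int, x: np.ndarray) -> np.ndarray:
    return lpmv(1, n, x)
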