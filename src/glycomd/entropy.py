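"""Quasiharmonic (QH) vibrational entropy with infinite-sampling
extrapolation, and Karplus-Kushick (KK) torsional conformational entropy.

QH: the mass-weighted covariance of Cartesian fluctuations is diagonalised;
each eigenvalue lambda (amu A^2) defines a quasiharmonic mode of frequency
omega = sqrt(kB T / lambda) whose entropy is the quantum harmonic-oscillator
value S/kB = x/(e^x - 1) - ln(1 - e^-x), x = hbar omega / kB T. Frames are
least-squares superposed on the selection's mean structure first, and the
six near-zero external (rigid-body) modes are dropped. Because QH entropy
creeps up with simulation length, it is evaluated on nested time windows
and extrapolated linearly in 1/t to the infinite-sampling intercept.

KK: the entropy of a torsion ensemble is that of the Gaussian with the same
covariance, S = (kB/2) ln[(2 pi e)^n det Sigma], with angles unwrapped
about their circular means; the bound-minus-free difference gives the
conformational penalty -T dS_qC.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import constants as C
from .errors import (
    AssemblyError,
    InsufficientSamplingError,
    ParameterError,
)
from .model import Trajectory
from .pose import kabsch_superpose

__all__ = [
    "EntropySeries",
    "EntropyEstimate",
    "quasiharmonic_entropy",
    "entropy_window_series",
    "extrapolate_entropy",
    "torsional_entropy_kk",
    "assemble_entropy",
]


@dataclass
class EntropySeries:
    """QH entropy evaluated on nested cumulative windows [0, t]."""

    window_ends: np.ndarray   # ns
    values: np.ndarray        # cal/(mol K)
    selection: str = ""


@dataclass
class EntropyEstimate:
    """Entropic penalty terms at temperature T, reported as -T dS in
    kcal/mol (positive values oppose binding)."""

    minus_t_ds_rtv: float
    minus_t_ds_qc: float
    temperature: float
    per_run_rtv: Optional[np.ndarray] = None
    sd_rtv: float = 0.0
    fit_slope: float = 0.0
    fit_intercept: float = 0.0

    @property
    def minus_t_ds_total(self) -> float:
        return self.minus_t_ds_rtv + self.minus_t_ds_qc

    @property
    def sd_total(self) -> float:
        return self.sd_rtv


def _mode_entropies(eigvals: np.ndarray, T: float) -> np.ndarray:
    """Per-mode quantum HO entropies, cal/(mol K), for eigenvalues in
    amu A^2."""
    lam_si = np.clip(eigvals, 0.0, None) * C.AMU_SI * C.ANGSTROM_SI ** 2
    with np.errstate(divide="ignore"):
        x = C.HBAR_SI / np.sqrt(C.KB_SI * T * lam_si)
    s = np.zeros_like(x)
    finite = np.isfinite(x) & (x < 700)
    xf = x[finite]
    s[finite] = C.R_CAL * (xf / np.expm1(xf) - np.log1p(-np.exp(-xf)))
    return s


def quasiharmonic_entropy(
    traj: Trajectory,
    selection: str,
    masses: Optional[np.ndarray] = None,
    T: float = C.DEFAULT_TEMPERATURE,
    superpose: bool = True,
    drop_modes: Optional[int] = None,
    frame_slice: slice = slice(None),
) -> float:
    """QH entropy of a selection, cal/(mol K).

    ``masses`` is per-selected-atom (amu); when omitted all atoms weigh
    1 amu. ``drop_modes`` defaults to 6 when superposition is applied (the
    rigid-body modes removed by the fit) and 0 otherwise.
    """
    idx = traj.topology.group(selection)
    frames = traj.frames[frame_slice]
    if len(frames) < 10:
        raise InsufficientSamplingError(
            f"{len(frames)} frames; at least 10 required for QH entropy"
        )
    coords = np.stack([f.coordinates[idx] for f in frames])
    if superpose:
        # two-pass: fit to first frame, then to the running mean
        ref = coords[0]
        for _ in range(2):
            fitted = np.empty_like(coords)
            for k in range(coords.shape[0]):
                sup = kabsch_superpose(coords[k], ref)
                fitted[k] = sup.apply(coords[k])
            ref = fitted.mean(axis=0)
            coords = fitted
    n_at = idx.size
    m = np.ones(n_at) if masses is None else np.asarray(masses, dtype=float)
    if m.size != n_at:
        raise ParameterError("masses length must match selection size")
    flat = coords.reshape(coords.shape[0], -1)
    flat = flat - flat.mean(axis=0)
    w = np.sqrt(np.repeat(m, 3))
    cov = np.cov(flat * w, rowvar=False, bias=True)
    eigvals = np.linalg.eigvalsh(np.atleast_2d(cov))
    if drop_modes is None:
        drop_modes = 6 if superpose else 0
    if drop_modes:
        eigvals = np.sort(eigvals)[drop_modes:]
    return float(_mode_entropies(eigvals, T).sum())


def entropy_window_series(
    traj: Trajectory,
    selection: str,
    masses: Optional[np.ndarray] = None,
    T: float = C.DEFAULT_TEMPERATURE,
    n_windows: int = 10,
    **kw,
) -> EntropySeries:
    """QH entropy on nested cumulative windows whose endpoints are evenly
    spaced in 1/t between t_total/n_windows and t_total."""
    if n_windows < 3:
        raise ParameterError("need at least 3 windows")
    times = traj.times
    t0 = times[0]
    t_total = times[-1] - t0
    inv = np.linspace(n_windows / t_total, 1.0 / t_total, n_windows)
    ends = 1.0 / inv
    values = []
    kept_ends = []
    for t_end in sorted(ends):
        n = int(np.searchsorted(times, t0 + t_end, side="right"))
        if n < 10:
            continue
        values.append(
            quasiharmonic_entropy(
                traj, selection, masses=masses, T=T, frame_slice=slice(0, n), **kw
            )
        )
        kept_ends.append(t_end)
    if len(values) < 3:
        raise InsufficientSamplingError("fewer than 3 usable entropy windows")
    return EntropySeries(
        window_ends=np.asarray(kept_ends), values=np.asarray(values),
        selection=selection,
    )


def extrapolate_entropy(series: EntropySeries) -> Tuple[float, float, float]:
    """OLS fit of S against 1/t; returns (intercept, slope, r_squared).

    The intercept is the QH entropy extrapolated to infinite sampling."""
    if series.values.size < 3:
        raise ParameterError("need at least 3 windows to extrapolate")
    x = 1.0 / np.asarray(series.window_ends, dtype=float)
    y = np.asarray(series.values, dtype=float)
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = ((y - y.mean()) ** 2).sum()
    ss_res = ((y - A @ [slope, intercept]) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(intercept), float(slope), float(r2)


# ---------------------------------------------------------------------------
# Karplus-Kushick torsional entropy
# ---------------------------------------------------------------------------


def _circular_mean_deg(samples: np.ndarray) -> np.ndarray:
    rad = np.radians(samples)
    return np.degrees(np.arctan2(np.sin(rad).mean(axis=0), np.cos(rad).mean(axis=0)))


def _unwrap_about_mean(samples: np.ndarray) -> np.ndarray:
    mu = _circular_mean_deg(samples)
    d = (samples - mu + 180.0) % 360.0 - 180.0
    return d + mu


def gaussian_torsion_entropy(samples_deg: np.ndarray) -> float:
    """KK entropy of one ensemble, cal/(mol K): Gaussian estimate from the
    covariance of the unwrapped angles in radians."""
    samples = np.atleast_2d(np.asarray(samples_deg, dtype=float))
    if samples.ndim != 2:
        raise ParameterError("samples must be (n_samples, n_torsions)")
    unwrapped = np.radians(_unwrap_about_mean(samples))
    n = unwrapped.shape[1]
    cov = np.cov(unwrapped, rowvar=False, bias=False)
    cov = np.atleast_2d(cov)
    variances = np.diag(cov)
    if np.any(variances < 1e-15):
        frozen = int(np.argmin(variances))
        raise ParameterError(
            f"torsion {frozen} has (near-)zero variance; covariance is singular"
        )
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ParameterError(
            "singular torsion covariance; a torsion may be frozen or duplicated"
        )
    return float(0.5 * C.R_CAL * (n * np.log(2.0 * np.pi * np.e) + logdet))


def torsional_entropy_kk(
    bound_deg: np.ndarray,
    free_deg: np.ndarray,
    T: float = C.DEFAULT_TEMPERATURE,
) -> float:
    """-T dS_qC (kcal/mol) for the bound-vs-free torsion ensembles.

    Positive when binding narrows the torsional distributions. Warns when an
    ensemble looks multimodal (KK assumes unimodality)."""
    bound = np.atleast_2d(np.asarray(bound_deg, dtype=float))
    free = np.atleast_2d(np.asarray(free_deg, dtype=float))
    if bound.shape[1] != free.shape[1]:
        raise ParameterError("bound and free ensembles must share torsions")
    for name, ens in (("bound", bound), ("free", free)):
        spread = np.degrees(
            np.sqrt(np.var(np.radians(_unwrap_about_mean(ens)), axis=0))
        )
        if np.any(spread > 120.0):
            warnings.warn(
                f"{name} ensemble has a torsion with circular SD > 120 deg; "
                "the unimodal Gaussian assumption is doubtful"
            )
    s_bound = gaussian_torsion_entropy(bound)
    s_free = gaussian_torsion_entropy(free)
    return float(-T * (s_bound - s_free) / 1000.0)


def assemble_entropy(
    complex_intercepts: Sequence[float],
    receptor_intercepts: Sequence[float],
    ligand_intercepts: Sequence[float],
    minus_t_ds_qc: float,
    T: float = C.DEFAULT_TEMPERATURE,
) -> EntropyEstimate:
    """Combine per-run QH intercepts (cal/(mol K)) for complex, receptor and
    ligand with the KK result into the total entropic penalty.

    -T dS_RTV per run = -T (S_complex - S_receptor - S_ligand) / 1000;
    total = -T dS_RTV + (-T dS_qC)."""
    c = np.asarray(complex_intercepts, dtype=float)
    r = np.asarray(receptor_intercepts, dtype=float)
    l = np.asarray(ligand_intercepts, dtype=float)
    if not (c.size == r.size == l.size) or c.size == 0:
        raise AssemblyError("per-run intercept lists must be equal-length, non-empty")
    per_run = -T * (c - r - l) / 1000.0
    return EntropyEstimate(
        minus_t_ds_rtv=float(per_run.mean()),
        minus_t_ds_qc=float(minus_t_ds_qc),
        temperature=T,
        per_run_rtv=per_run,
        sd_rtv=float(per_run.std(ddof=1)) if per_run.size > 1 else 0.0,
    )
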