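"""Chemical shift encoding water-fat separation and PDFF mapping.

Signal model per voxel at echo time t (seconds)::

    s(t) = (rho_W + rho_F * sum_p alpha_p exp(i 2 pi f_p t))
           * exp(i 2 pi psi t) * exp(-R2* t)

with a multi-peak fat spectrum (frequency offsets f_p in Hz at the scanner
field strength, amplitudes alpha_p summing to 1), a smooth field map psi
(Hz) and a single effective transverse relaxation rate R2* (1/s) shared by
water and fat. Proton density fat fraction is
PDFF = 100 * rho_F / (rho_W + rho_F) with magnitudes of the fitted complex
amplitudes.

Fitting is voxel-independent variable projection (VARPRO): for every
candidate (psi, R2*) on a grid the two complex amplitudes are solved in
closed form, the minimum-residual candidate is refined by bounded local
optimization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FatSpectrum",
    "EchoSeries",
    "VoxelFit",
    "PDFFMap",
    "default_echo_times_ms",
    "forward_signal",
    "fit_voxel",
    "map_volume",
    "vertebra_pdff",
]

GAMMA_HZ_PER_T = 42.577478518e6  # proton gyromagnetic ratio / 2pi

# Published bone-marrow triglyceride spectrum: chemical shifts of the seven
# fat resonances relative to water (ppm) and their relative proton densities.
_MARROW_PPM = np.array([0.60, -0.50, -1.95, -2.46, -2.68, -3.10, -3.40])
_MARROW_AMP = np.array([0.047, 0.039, 0.006, 0.120, 0.044, 0.656, 0.088])


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat spectrum: frequency offsets (Hz) and amplitudes."""

    freqs_hz: np.ndarray
    amps: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "freqs_hz", np.asarray(self.freqs_hz, dtype=float))
        object.__setattr__(self, "amps", np.asarray(self.amps, dtype=float))
        if self.freqs_hz.shape != self.amps.shape:
            raise ValueError("frequencies and amplitudes must align")
        if np.any(self.amps <= 0):
            raise ValueError("spectrum amplitudes must be positive")
        if not np.isclose(self.amps.sum(), 1.0):
            raise ValueError("spectrum amplitudes must sum to 1")

    @classmethod
    def marrow_7peak(cls, field_strength_t: float = 3.0) -> "FatSpectrum":
        f = _MARROW_PPM * GAMMA_HZ_PER_T * field_strength_t * 1e-6
        a = _MARROW_AMP / _MARROW_AMP.sum()
        return cls(f, a)

    @classmethod
    def single_peak(cls, freq_hz: float = -434.0) -> "FatSpectrum":
        return cls(np.array([freq_hz]), np.array([1.0]))

    def phasor(self, t_s: np.ndarray) -> np.ndarray:
        """Complex fat dephasing factor sum_p alpha_p e^{i 2 pi f_p t}."""
        t_s = np.asarray(t_s, dtype=float)
        return (self.amps * np.exp(2j * np.pi * np.outer(t_s, self.freqs_hz))).sum(
            axis=-1)


def default_echo_times_ms(n_echoes: int = 6, te_min_ms: float = 1.12,
                          delta_te_ms: float = 0.96) -> np.ndarray:
    """Six-echo monopolar gradient-echo timing (TEmin 1.12 ms, dTE 0.96 ms)."""
    return te_min_ms + delta_te_ms * np.arange(n_echoes)


@dataclass
class EchoSeries:
    """Complex multi-echo signals: shape (..., n_echoes), echo times in ms."""

    signal: np.ndarray
    echo_times_ms: np.ndarray

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=complex)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if self.signal.shape[-1] != len(self.echo_times_ms):
            raise ValueError("last signal axis must match the number of echoes")
        if np.any(np.diff(self.echo_times_ms) <= 0):
            raise ValueError("echo times must be strictly increasing")

    def to_nifti(self, path: str, sidecar_path: str | None = None) -> None:
        """4D NIfTI (last axis = echo) holding |s| and angle interleaved is
        lossy; store real and imaginary stacked on a 5th axis instead."""
        import nibabel as nib

        arr = np.stack([self.signal.real, self.signal.imag], axis=-1)
        nib.save(nib.Nifti1Image(arr.astype(np.float32), np.eye(4)), path)
        if sidecar_path:
            with open(sidecar_path, "w") as fh:
                json.dump({"EchoTimesMs": list(map(float, self.echo_times_ms))}, fh)

    @classmethod
    def from_nifti(cls, path: str, sidecar_path: str) -> "EchoSeries":
        import nibabel as nib

        arr = np.asanyarray(nib.load(path).dataobj)
        with open(sidecar_path) as fh:
            te = np.asarray(json.load(fh)["EchoTimesMs"], dtype=float)
        return cls(arr[..., 0] + 1j * arr[..., 1], te)


@dataclass
class VoxelFit:
    rho_w: float
    rho_f: float
    psi_hz: float
    r2star: float
    residual: float
    degenerate: bool = False

    @property
    def pdff_percent(self) -> float:
        tot = self.rho_w + self.rho_f
        if self.degenerate or tot <= 0:
            return np.nan
        return 100.0 * self.rho_f / tot


@dataclass
class PDFFMap:
    pdff: np.ndarray  # %, nan outside mask / degenerate
    r2star: np.ndarray
    psi: np.ndarray
    n_degenerate: int = 0


def forward_signal(rho_w, rho_f, psi_hz, r2star, echo_times_ms,
                   spectrum: FatSpectrum) -> np.ndarray:
    """Evaluate the water-fat signal model; broadcasts over voxel maps.

    Parameters are broadcast against each other; the returned array gains a
    trailing echo axis.
    """
    te_s = np.asarray(echo_times_ms, dtype=float) * 1e-3
    rho_w, rho_f, psi_hz, r2star = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (rho_w, rho_f, psi_hz, r2star)))
    for name, a in (("rho_w", rho_w), ("rho_f", rho_f), ("psi", psi_hz),
                    ("r2star", r2star)):
        if not np.all(np.isfinite(a)):
            raise ValueError(f"{name} must be finite")
    cf = spectrum.phasor(te_s)  # (ne,)
    shape = rho_w.shape + (len(te_s),)
    rw = rho_w[..., None]
    rf = rho_f[..., None]
    phase = np.exp((2j * np.pi * psi_hz[..., None] - r2star[..., None]) * te_s)
    return ((rw + rf * cf) * phase).reshape(shape)


def _design(te_s: np.ndarray, spectrum: FatSpectrum, psi_hz, r2star) -> np.ndarray:
    """VARPRO design matrix columns [water, fat] for given (psi, R2*)."""
    cf = spectrum.phasor(te_s)
    w = np.exp((2j * np.pi * np.asarray(psi_hz)[..., None]
                - np.asarray(r2star)[..., None]) * te_s)
    return np.stack([w, w * cf], axis=-1)  # (..., ne, 2)


def _amplitudes_and_residual(A: np.ndarray, s: np.ndarray):
    """Least-squares complex amplitudes and residual energy, broadcast."""
    AH = np.conjugate(np.swapaxes(A, -1, -2))
    G = AH @ A[..., :, :]
    b = (AH @ s[..., :, None])
    amps = np.linalg.solve(G, b)[..., 0]
    resid = s - (A @ amps[..., None])[..., 0]
    return amps, np.real(np.sum(resid * np.conjugate(resid), axis=-1))


def fit_voxel(signal: np.ndarray, echo_times_ms: np.ndarray,
              spectrum: FatSpectrum | None = None,
              psi_search_hz: np.ndarray | None = None,
              r2star_search: np.ndarray | None = None,
              refine: bool = True) -> VoxelFit:
    """VARPRO fit of one voxel's multi-echo signal.

    Grid-search (psi, R2*), closed-form complex amplitudes per candidate,
    then bounded local refinement of the nonlinear pair from the best grid
    point. Magnitudes of the complex amplitudes give rho_W and rho_F.
    """
    signal = np.asarray(signal, dtype=complex)
    if signal.ndim != 1 or len(signal) < 4:
        raise ValueError("need a 1D signal with at least 4 echoes")
    if np.all(signal == 0):
        return VoxelFit(0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    spectrum = spectrum or FatSpectrum.marrow_7peak()
    te_s = np.asarray(echo_times_ms, dtype=float) * 1e-3
    psi = np.arange(-150.0, 150.0 + 1e-9, 2.0) if psi_search_hz is None \
        else np.asarray(psi_search_hz, dtype=float)
    r2 = np.arange(0.0, 300.0 + 1e-9, 25.0) if r2star_search is None \
        else np.asarray(r2star_search, dtype=float)

    P, R = np.meshgrid(psi, r2, indexing="ij")
    A = _design(te_s, spectrum, P.ravel(), R.ravel())
    amps, res = _amplitudes_and_residual(A, signal)
    best = int(np.argmin(res))
    p0, r0 = P.ravel()[best], R.ravel()[best]

    if refine:
        def resid_vec(x):
            Ax = _design(te_s, spectrum, x[0], x[1])
            amp_, _ = _amplitudes_and_residual(Ax, signal)
            r_ = signal - Ax @ amp_
            return np.concatenate([r_.real, r_.imag])

        span = np.ptp(psi) if len(psi) > 1 else 100.0
        sol = least_squares(
            resid_vec, x0=[p0, max(r0, 1e-3)],
            bounds=([psi.min() - 0.1 * span, 0.0],
                    [psi.max() + 0.1 * span, max(r2.max() * 2, 500.0)]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, diff_step=1e-6)
        p0, r0 = float(sol.x[0]), float(sol.x[1])

    Ab = _design(te_s, spectrum, p0, r0)
    amp, res_f = _amplitudes_and_residual(Ab, signal)
    return VoxelFit(float(np.abs(amp[0])), float(np.abs(amp[1])),
                    float(p0), float(r0), float(res_f))


def map_volume(echoes: EchoSeries, mask=None,
               spectrum: FatSpectrum | None = None,
               psi_search_hz: np.ndarray | None = None,
               r2star_search: np.ndarray | None = None,
               refine: bool = True) -> PDFFMap:
    """Fit every masked voxel; PDFF = 100 rho_F / (rho_W + rho_F).

    Unmasked and degenerate voxels are NaN in the output maps.
    """
    sig = echoes.signal
    vol_shape = sig.shape[:-1]
    if mask is None:
        sel = np.ones(vol_shape, dtype=bool)
    else:
        sel = mask.binary() if hasattr(mask, "binary") else np.asarray(mask, bool)
        if sel.shape != vol_shape:
            raise ValueError("mask shape does not match echo volume")
    pdff = np.full(vol_shape, np.nan)
    r2 = np.full(vol_shape, np.nan)
    psi = np.full(vol_shape, np.nan)
    n_degen = 0
    if not sel.any():
        import warnings

        warnings.warn("empty mask: PDFF map has no fitted voxels")
        return PDFFMap(pdff, r2, psi, 0)
    for idx in np.argwhere(sel):
        fit = fit_voxel(sig[tuple(idx)], echoes.echo_times_ms, spectrum,
                        psi_search_hz, r2star_search, refine)
        if fit.degenerate:
            n_degen += 1
            continue
        t = tuple(idx)
        pdff[t] = fit.pdff_percent
        r2[t] = fit.r2star
        psi[t] = fit.psi_hz
    return PDFFMap(pdff, r2, psi, n_degen)


def vertebra_pdff(pdff_map: PDFFMap, mask, level: str) -> float:
    """Mean PDFF (%) over one vertebra's voxels, NaN voxels excluded."""
    label = mask.level_label(level)
    vals = pdff_map.pdff[mask.labels == label]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError(f"no fitted voxels for level {level}")
    return float(vals.mean())
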