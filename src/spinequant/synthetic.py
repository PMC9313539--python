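"""Synthetic inputs: CT phantoms, multi-echo MRI signals and cohort tables.

The CT phantom is a vertebral-body-like elliptic cylinder: a dense cortical
shell around a stochastic trabecular interior, in air. Two conditions are
modelled: an osteoporotic interior (low mean HU, Normal(80, 30)) and a
diffusely sclerotic osteoblastic interior (high mean HU, Normal(600, 150)),
shell at 1200 HU, air at -1000 HU. Posterior elements, endplate curvature
and fracture morphology are deliberately not modelled.

The echo generator evaluates the forward water-fat signal model of
:mod:`spinequant.pdff` voxel-wise, with optional complex Gaussian noise
(SNR = first-echo magnitude / noise standard deviation).

The cohort generator draws per-vertebra measures from group-specific
log-normal distributions whose default medians are the published pooled
group medians (PDFF 11.9 vs 43.8 %, failure displacement 0.874 vs 0.348 mm,
failure load 29589 vs 3095 N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HU_MAX, HU_MIN, CTVolume, SegmentationMask
from .fixtures import table1_fixture  # re-exported: fixture is part of this surface
from .pdff import EchoSeries, FatSpectrum, forward_signal

__all__ = [
    "PhantomTruth",
    "make_vertebra_phantom",
    "make_cse_echoes",
    "make_cohort",
    "table1_fixture",
    "cohort_to_csv",
    "cohort_from_csv",
]

COHORT_COLUMNS = ["patient_id", "group", "level", "fractured", "pdff_percent",
                  "failure_displacement_mm", "failure_load_N"]


@dataclass
class PhantomTruth:
    """Ground-truth parameters of a vertebral-body CT phantom."""

    condition: str  # "osteoporotic" | "osteoblastic"
    trabecular_hu_mean: float
    trabecular_hu_sd: float
    shell_hu: float = 1200.0
    a_mm: float = 14.0  # outer semi-axis, x
    b_mm: float = 11.0  # outer semi-axis, y
    height_mm: float = 24.0  # commensurate with 1.5 and 2.0 mm mesh cells
    shell_thickness_mm: float = 1.5
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_mm: float = 2.0
    # correlation length of the trabecular texture: real trabecular HU
    # fields are smooth at the mm scale, not white at voxel scale; the
    # marginal sd stays trabecular_hu_sd. 0 gives white voxel noise.
    texture_sigma_mm: float = 1.2
    psf_sigma_mm: float = 0.0  # optional scanner point-spread emulation
    seed: int = 0

    def __post_init__(self):
        if self.shell_hu <= self.trabecular_hu_mean:
            raise ValueError("shell must be denser than the trabecular interior")
        if self.shell_thickness_mm * 2 >= min(self.a_mm, self.b_mm, self.height_mm):
            raise ValueError("shell thickness incompatible with geometry")

    @classmethod
    def osteoporotic(cls, seed: int = 0, **kw) -> "PhantomTruth":
        """Low-HU trabecular interior; the cortical shell is thinned and
        porous in osteoporosis and partial-volume averaging lowers its
        imaged HU further, hence the moderate shell default."""
        kw.setdefault("shell_hu", 500.0)
        kw.setdefault("trabecular_hu_mean", 80.0)
        kw.setdefault("trabecular_hu_sd", 30.0)
        return cls("osteoporotic", seed=seed, **kw)

    @classmethod
    def osteoblastic(cls, seed: int = 0, **kw) -> "PhantomTruth":
        """Diffusely sclerotic interior; osteoblastic disease deposits
        woven bone in the cortex as well, hence the dense shell."""
        kw.setdefault("shell_hu", 1200.0)
        kw.setdefault("trabecular_hu_mean", 600.0)
        kw.setdefault("trabecular_hu_sd", 150.0)
        return cls("osteoblastic", seed=seed, **kw)


def make_vertebra_phantom(truth: PhantomTruth,
                          grid_shape: tuple[int, int, int] | None = None
                          ) -> tuple[CTVolume, SegmentationMask]:
    """Build the phantom CT volume and its segmentation mask.

    Deterministic given ``truth.seed``. The mask (label 1 = "L1") covers
    exactly the solid (shell + interior).
    """
    sp = np.asarray(truth.spacing, dtype=float)
    need = np.array([2 * truth.a_mm, 2 * truth.b_mm, truth.height_mm]) \
        + 2 * truth.margin_mm
    shape = np.ceil(need / sp).astype(int) if grid_shape is None \
        else np.asarray(grid_shape, dtype=int)
    if np.any(shape * sp < np.array([2 * truth.a_mm, 2 * truth.b_mm,
                                     truth.height_mm])):
        raise ValueError("phantom geometry exceeds the requested grid")

    center = shape * sp / 2.0
    ii = np.indices(tuple(shape)).astype(float)
    x = (ii[0] + 0.5) * sp[0] - center[0]
    y = (ii[1] + 0.5) * sp[1] - center[1]
    z = (ii[2] + 0.5) * sp[2] - center[2]

    t = truth.shell_thickness_mm
    solid = ((x / truth.a_mm) ** 2 + (y / truth.b_mm) ** 2 <= 1.0) \
        & (np.abs(z) <= truth.height_mm / 2.0)
    interior = ((x / (truth.a_mm - t)) ** 2 + (y / (truth.b_mm - t)) ** 2 <= 1.0) \
        & (np.abs(z) <= truth.height_mm / 2.0 - t)

    rng = np.random.default_rng(truth.seed)
    data = np.full(tuple(shape), -1000.0)
    data[solid] = truth.shell_hu
    if truth.trabecular_hu_sd > 0:
        noise = rng.standard_normal(tuple(shape))
        if truth.texture_sigma_mm > 0:
            from scipy.ndimage import gaussian_filter

            noise = gaussian_filter(noise, truth.texture_sigma_mm / sp,
                                    mode="nearest")
            noise /= noise[interior].std()  # keep the marginal sd
        data[interior] = truth.trabecular_hu_mean \
            + truth.trabecular_hu_sd * noise[interior]
    else:
        data[interior] = truth.trabecular_hu_mean
    if truth.psf_sigma_mm > 0:
        # emulate the scanner point-spread function: real CT never shows a
        # razor-sharp cortex/air transition at the voxel scale
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(data, truth.psf_sigma_mm / sp, mode="nearest")
    np.clip(data, HU_MIN, HU_MAX, out=data)

    ct = CTVolume(data, tuple(sp))
    mask = SegmentationMask(solid.astype(np.int32), {1: "L1"})
    return ct, mask


def make_cse_echoes(pdff_truth_map: np.ndarray, r2star_map: np.ndarray,
                    field_map_hz: np.ndarray, echo_times_ms: np.ndarray,
                    snr: float | None = None, seed: int = 0,
                    spectrum: FatSpectrum | None = None) -> EchoSeries:
    """Forward-simulate complex multi-echo signals from parameter maps.

    Water and fat magnitudes sum to 1 per voxel with fat fraction taken
    from ``pdff_truth_map`` (fractions in [0, 1]). With ``snr`` given,
    independent complex Gaussian noise is added per voxel per echo with
    standard deviation |s(TE1)| / snr (E|n|^2 = sd^2).
    """
    pdff = np.asarray(pdff_truth_map, dtype=float)
    r2s = np.asarray(r2star_map, dtype=float)
    psi = np.asarray(field_map_hz, dtype=float)
    if not (pdff.shape == r2s.shape == psi.shape):
        raise ValueError("pdff, r2star and field maps must share a shape")
    if np.any((pdff < 0) | (pdff > 1)):
        raise ValueError("pdff truth must be fractions in [0, 1]")
    spectrum = spectrum or FatSpectrum.marrow_7peak()
    sig = forward_signal(1.0 - pdff, pdff, psi, r2s, echo_times_ms, spectrum)
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        sd = np.abs(sig[..., 0]) / snr
        noise = (rng.standard_normal(sig.shape)
                 + 1j * rng.standard_normal(sig.shape)) / np.sqrt(2.0)
        sig = sig + sd[..., None] * noise
    return EchoSeries(sig, np.asarray(echo_times_ms, dtype=float))


# default pooled medians per group, used as log-normal location parameters
_GROUP_MEDIANS = {
    "metastasis": {"pdff_percent": 11.9, "failure_displacement_mm": 0.874,
                   "failure_load_N": 29589.0},
    "osteoporosis": {"pdff_percent": 43.8, "failure_displacement_mm": 0.348,
                     "failure_load_N": 3095.0},
}
# log-space spreads chosen to echo the published within-group scatter
_LOG_SD = {"pdff_percent": 0.35, "failure_displacement_mm": 0.20,
           "failure_load_N": 0.30}
_PATIENT_LOG_SD = 0.15


def make_cohort(n_metastasis: int, n_osteoporosis: int,
                effect_profile: float | dict[str, float] = 1.0,
                seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort table (no fractures flagged).

    ``effect_profile`` scales the log-scale between-group separation per
    measure: 1 keeps the default group medians, 0 collapses both groups
    onto their common geometric-mean median (null configuration).
    """
    if n_metastasis < 1 or n_osteoporosis < 1:
        raise ValueError("group sizes must be >= 1")
    if np.isscalar(effect_profile):
        effect = {m: float(effect_profile) for m in _LOG_SD}
    else:
        effect = {m: float(effect_profile.get(m, 1.0)) for m in _LOG_SD}

    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for group, n in (("metastasis", n_metastasis),
                     ("osteoporosis", n_osteoporosis)):
        for _ in range(n):
            pid += 1
            pshift = {m: _PATIENT_LOG_SD * rng.standard_normal()
                      for m in _LOG_SD}
            for lev in ("L1", "L2", "L3", "L4"):
                row = {"patient_id": pid, "group": group, "level": lev,
                       "fractured": False}
                for m in _LOG_SD:
                    lm = np.log(_GROUP_MEDIANS[group][m])
                    lo = np.log(_GROUP_MEDIANS["metastasis"][m]
                                * _GROUP_MEDIANS["osteoporosis"][m]) / 2.0
                    loc = lo + effect[m] * (lm - lo)
                    val = np.exp(loc + pshift[m]
                                 + _LOG_SD[m] * rng.standard_normal())
                    if m == "pdff_percent":
                        val = float(np.clip(val, 0.0, 100.0))
                    row[m] = val
                rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def cohort_to_csv(table: pd.DataFrame, path: str) -> None:
    table[COHORT_COLUMNS].to_csv(path, index=False)


def cohort_from_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    df["fractured"] = df["fractured"].astype(bool)
    return df
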