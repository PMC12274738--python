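"""Two-wavelength hemoglobin unmixing: sO2 and relative C_HbT maps.

The photoacoustic amplitude at wavelength lambda is proportional to the
local absorption coefficient,

    PA(lambda) = k * [eps_HbO2(lambda) * C_HbO2 + eps_Hb(lambda) * C_Hb],

with a shared proportionality constant k (Grueneisen parameter times local
fluence) that is assumed wavelength independent and absorbed into relative
units.  With amplitudes at two wavelengths this is a 2x2 linear system per
pixel; its solution gives the oxygen saturation

    sO2 = C_HbO2 / (C_HbO2 + C_Hb)

and, because oxy- and deoxyhemoglobin absorb almost identically at 532 nm
(near-isosbestic), the 532 nm amplitude doubles as a relative total
hemoglobin concentration C_HbT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExtinctionTable",
    "FunctionalMaps",
    "forward_amplitudes",
    "unmix",
    "fractional_change_series",
    "estimate_background_noise",
]


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction pairs (eps_HbO2, eps_Hb) at the two laser lines."""

    wavelengths: tuple[float, float]
    eps_hbo2: tuple[float, float]
    eps_hb: tuple[float, float]
    source: str = ""

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.eps_hbo2 + self.eps_hb):
            raise ValueError("extinction coefficients must be strictly positive")
        # the system design leans on 532 nm being near-isosbestic
        i = self.wavelengths.index(532) if 532 in self.wavelengths else 0
        rel = abs(self.eps_hbo2[i] - self.eps_hb[i]) / self.eps_hbo2[i]
        if rel > 0.1:
            raise ValueError(
                f"first wavelength is not near-isosbestic (relative gap {rel:.3f} > 0.1)"
            )

    @property
    def matrix(self) -> np.ndarray:
        """Rows = wavelengths, columns = (HbO2, Hb)."""
        return np.array(
            [
                [self.eps_hbo2[0], self.eps_hb[0]],
                [self.eps_hbo2[1], self.eps_hb[1]],
            ]
        )

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """Packaged 532/558 nm table (standard compiled hemoglobin spectra)."""
        with resources.files("spiralscan.data").joinpath(
            "hemoglobin_extinction.csv"
        ).open() as fh:
            df = pd.read_csv(fh, comment="#")
        df = df.sort_values("wavelength_nm")
        return cls(
            wavelengths=tuple(df["wavelength_nm"]),
            eps_hbo2=tuple(df["eps_hbo2"]),
            eps_hb=tuple(df["eps_hb"]),
            source="packaged standard tabulation (see data file header)",
        )


@dataclass
class FunctionalMaps:
    """sO2 and relative C_HbT rasters with a validity mask.

    ``so2`` is defined only where ``mask`` is true and clamped to [0, 1];
    ``n_clamped`` counts pixels whose raw component estimates were negative.
    """

    so2: np.ndarray
    chbt_rel: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0
    amp_threshold: float = 0.0
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        m = self.mask
        return {
            "n_masked_pixels": int(m.sum()),
            "mean_so2": float(self.so2[m].mean()) if m.any() else float("nan"),
            "mean_chbt_rel": float(self.chbt_rel[m].mean()) if m.any() else float("nan"),
            "n_clamped": int(self.n_clamped),
            "amp_threshold": float(self.amp_threshold),
        }


def forward_amplitudes(
    so2: np.ndarray | float,
    chbt: np.ndarray | float,
    ext: ExtinctionTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless PA amplitudes at the two wavelengths (relative units).

    The inverse of :func:`unmix`; used by the phantom generator and by
    forward-inverse consistency tests.
    """
    if ext is None:
        ext = ExtinctionTable.default()
    so2 = np.asarray(so2, dtype=float)
    chbt = np.asarray(chbt, dtype=float)
    c_hbo2 = so2 * chbt
    c_hb = (1.0 - so2) * chbt
    M = ext.matrix
    pa0 = M[0, 0] * c_hbo2 + M[0, 1] * c_hb
    pa1 = M[1, 0] * c_hbo2 + M[1, 1] * c_hb
    return pa0, pa1


def estimate_background_noise(img: np.ndarray, fill_mask: np.ndarray) -> float:
    """Robust noise scale from filled pixels adjacent to unfilled ones.

    In a sparsely sampled raw image the filled pixels bordering gaps are
    dominated by background, so 1.4826 * MAD of their values estimates the
    acquisition noise sigma.  Returns 0 when the image is fully filled.
    """
    from scipy import ndimage

    if fill_mask.all():
        return 0.0
    near_gap = fill_mask & ndimage.binary_dilation(~fill_mask, np.ones((3, 3), bool))
    vals = img[near_gap]
    if vals.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(vals - np.median(vals))))


def _image_and_mask(img) -> tuple[np.ndarray, np.ndarray]:
    """Accept a ReconstructedImage or a bare array (fully filled)."""
    if hasattr(img, "pixels"):
        return np.asarray(img.pixels, dtype=float), np.asarray(img.fill_mask, dtype=bool)
    a = np.asarray(img, dtype=float)
    return a, np.ones_like(a, dtype=bool)


def unmix(
    img532,
    img558,
    ext: ExtinctionTable | None = None,
    amp_threshold: float | None = None,
) -> FunctionalMaps:
    """Per-pixel two-wavelength linear unmixing of co-registered images.

    Solves ``PA = M @ (k*C_HbO2, k*C_Hb)`` on every pixel where both
    wavelengths were sampled and the 532 nm amplitude exceeds
    ``amp_threshold`` (default: 5x the background noise estimate of the
    532 nm image).  Negative component estimates are clamped to zero and
    counted.  ``chbt_rel = PA(532) / (sO2*eps_HbO2(532) +
    (1-sO2)*eps_Hb(532))``, in relative units.
    """
    if ext is None:
        ext = ExtinctionTable.default()
    pa0, m0 = _image_and_mask(img532)
    pa1, m1 = _image_and_mask(img558)
    if pa0.shape != pa1.shape:
        raise ValueError("the two wavelength images must share a grid")
    M = ext.matrix
    det = float(np.linalg.det(M))
    if abs(det) < 1e-12 * float(np.abs(M).max()) ** 2:
        raise ValueError("extinction rows are proportional: system is singular")
    if amp_threshold is None:
        amp_threshold = 5.0 * estimate_background_noise(pa0, m0)
    mask = m0 & m1 & (pa0 > amp_threshold)

    # analytic 2x2 inverse, vectorised
    c_hbo2 = (M[1, 1] * pa0 - M[0, 1] * pa1) / det
    c_hb = (-M[1, 0] * pa0 + M[0, 0] * pa1) / det
    neg = mask & ((c_hbo2 < 0) | (c_hb < 0))
    n_clamped = int(neg.sum())
    c_hbo2 = np.clip(c_hbo2, 0.0, None)
    c_hb = np.clip(c_hb, 0.0, None)

    total = c_hbo2 + c_hb
    so2 = np.zeros_like(pa0)
    ok = mask & (total > 0)
    so2[ok] = np.clip(c_hbo2[ok] / total[ok], 0.0, 1.0)

    eps_mix = so2 * M[0, 0] + (1.0 - so2) * M[0, 1]
    chbt = np.zeros_like(pa0)
    chbt[mask] = pa0[mask] / eps_mix[mask]

    return FunctionalMaps(
        so2=so2,
        chbt_rel=chbt,
        mask=mask,
        n_clamped=n_clamped,
        amp_threshold=float(amp_threshold),
        meta={"det": det, "wavelengths": list(ext.wavelengths)},
    )


def fractional_change_series(
    maps: "list[FunctionalMaps] | pd.DataFrame",
    baseline_frames: int = 5,
) -> pd.DataFrame:
    """Per-frame fractional change of FOV-mean sO2 and C_HbT vs baseline.

    The baseline is the mean of the first ``baseline_frames`` FOV means;
    each frame then reports ``(value - baseline) / baseline``.  Accepts a
    list of :class:`FunctionalMaps` or a DataFrame with ``mean_so2`` /
    ``mean_chbt_rel`` columns.
    """
    if isinstance(maps, pd.DataFrame):
        df = maps[["mean_so2", "mean_chbt_rel"]].reset_index(drop=True)
    else:
        df = pd.DataFrame([m.summary() for m in maps])[["mean_so2", "mean_chbt_rel"]]
    if len(df) < baseline_frames:
        raise ValueError("need at least baseline_frames frames")
    base = df.iloc[:baseline_frames].mean()
    if (base == 0).any() or base.isna().any():
        raise ValueError("zero or undefined baseline")
    out = (df - base) / base
    out.columns = ["so2_fractional_change", "chbt_fractional_change"]
    out.insert(0, "frame", np.arange(len(df)))
    return out
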