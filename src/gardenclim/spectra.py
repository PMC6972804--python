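"""Leaf reflectance spectra and the two spectral trait indices.

A field spectroradiometer records % reflectance on a 1-nm grid; three
leaves per tree are averaged band-wise and two narrow-band indices are
computed from the averaged spectrum:

* PRI, the photochemical reflectance index,
  (R531 - R570) / (R531 + R570), sensitive to xanthophyll-cycle
  activity and hence radiation-use efficiency;
* mND705, the modified red-edge normalised difference index,
  (R750 - R705) / (R750 + R705 - 2 R445), a chlorophyll proxy robust
  to leaf surface structure, referred to as "NDVI" in outputs.

Both are ratios of reflectances, so they are invariant to uniform
rescaling of the spectrum (e.g. % vs fraction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gardenclim")

#: narrow bands (nm) that must be resolvable on the wavelength grid
REQUIRED_BANDS = (445, 531, 570, 705, 750)


class DegenerateSpectrumError(ValueError):
    """An index denominator vanished."""


@dataclass
class ReflectanceSpectrum:
    """Per-leaf % reflectance on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    tree_id: str = ""
    leaf_id: str = ""
    n_leaves: int = 1

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must align")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def band(self, nm: float, tolerance_nm: float = 2.0) -> float:
        """Reflectance at the grid point nearest ``nm``.

        Exact grid hits are used directly; otherwise the nearest
        neighbour within ``tolerance_nm`` is substituted and logged.
        """
        i = int(np.argmin(np.abs(self.wavelengths - nm)))
        gap = abs(self.wavelengths[i] - nm)
        if gap > tolerance_nm:
            raise ValueError(f"no band within {tolerance_nm} nm of {nm} nm")
        if gap > 0:
            logger.info("band %g nm absent; using %g nm", nm, self.wavelengths[i])
        return float(self.reflectance[i])


def average_spectra(spectra: Sequence[ReflectanceSpectrum]) -> ReflectanceSpectrum:
    """Band-wise arithmetic mean of several leaves from one tree.

    The pipeline averages spectra first and computes indices from the
    averaged spectrum; the reverse order gives a different (and not
    used) estimate because the indices are nonlinear.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != grid.shape or not np.array_equal(s.wavelengths, grid):
            raise ValueError("wavelength grids differ between leaves")
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    return ReflectanceSpectrum(grid.copy(), mean, tree_id=spectra[0].tree_id,
                               leaf_id="mean", n_leaves=len(spectra))


def pri(spectrum: ReflectanceSpectrum) -> float:
    """Photochemical reflectance index (R531 - R570)/(R531 + R570)."""
    r531, r570 = spectrum.band(531), spectrum.band(570)
    denom = r531 + r570
    if denom == 0:
        raise DegenerateSpectrumError("R531 + R570 is zero")
    return (r531 - r570) / denom


def ndvi_mnd705(spectrum: ReflectanceSpectrum) -> float:
    """Modified red-edge NDVI (R750 - R705)/(R750 + R705 - 2 R445)."""
    r750, r705, r445 = spectrum.band(750), spectrum.band(705), spectrum.band(445)
    denom = r750 + r705 - 2.0 * r445
    if denom == 0:
        raise DegenerateSpectrumError("R750 + R705 - 2 R445 is zero")
    return (r750 - r705) / denom


def tree_indices(spectra_by_tree: dict[str, Sequence[ReflectanceSpectrum]]) -> pd.DataFrame:
    """Average each tree's leaves, then compute both indices.

    Returns a frame with columns tree_id, PRI, NDVI, n_leaves.
    """
    rows = []
    for tree, leaves in spectra_by_tree.items():
        mean = average_spectra(list(leaves))
        rows.append({"tree_id": tree, "PRI": pri(mean),
                     "NDVI": ndvi_mnd705(mean), "n_leaves": mean.n_leaves})
    return pd.DataFrame(rows)


def read_spectra_csv(path, grid_check: bool = True) -> dict[str, list[ReflectanceSpectrum]]:
    """Read long-format spectra (tree_id, leaf_id, wavelength_nm,
    reflectance_pct) into per-tree lists of spectra."""
    df = pd.read_csv(path)
    out: dict[str, list[ReflectanceSpectrum]] = {}
    for (tree, leaf), grp in df.groupby(["tree_id", "leaf_id"], sort=True):
        grp = grp.sort_values("wavelength_nm")
        out.setdefault(str(tree), []).append(ReflectanceSpectrum(
            grp["wavelength_nm"].to_numpy(), grp["reflectance_pct"].to_numpy(),
            tree_id=str(tree), leaf_id=str(leaf)))
    return out


def write_spectra_csv(spectra_by_tree: dict[str, Iterable[ReflectanceSpectrum]], path) -> None:
    frames = []
    for tree, leaves in spectra_by_tree.items():
        for s in leaves:
            frames.append(pd.DataFrame({
                "tree_id": tree, "leaf_id": s.leaf_id,
                "wavelength_nm": s.wavelengths,
                "reflectance_pct": s.reflectance}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
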