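"""Projection of electrode-level power onto atlas regions.

Each electrode contributes to a region through a 3D isotropic Gaussian
(default 2 cm full-width at half-maximum) evaluated at the region's point
set.  Summed pre-normalisation weights give the electrode density used for
region retention (group-mean density > 3); retained regions' weights are
normalised across electrodes to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_FWHM_MM = 20.0
DENSITY_THRESHOLD = 3.0


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full-width at half-maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AtlasRegions:
    """Named point clouds (mm) standing in for atlas subdivisions.

    Left hemisphere is x <= 0 by convention (configurable via ``left_sign``).
    """

    regions: dict[str, np.ndarray]  # name -> (n_points, 3)
    left_sign: int = -1

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region names must be unique")
        for name, pts in self.regions.items():
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
                raise ValueError(f"region {name!r} must be a nonempty (n, 3) point set")
            self.regions[name] = pts

    @property
    def names(self) -> list[str]:
        return list(self.regions)


@dataclass
class ProjectionWeights:
    weights: dict[str, dict[str, float]]  # region -> electrode -> normalized weight
    density: dict[str, float]  # region -> pre-normalization weight sum
    retained: list[str] = field(default_factory=list)


def mirror_electrodes(positions: np.ndarray, hemisphere: str, left_sign: int = -1) -> np.ndarray:
    """Flip right-hemisphere electrode positions into the left hemisphere (x -> -x)."""
    positions = np.asarray(positions, dtype=float)
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    out = positions.copy()
    if hemisphere == "right":
        out[:, 0] = -out[:, 0]
    return out


def _raw_weights(
    positions: np.ndarray, electrode_names: list[str], atlas: AtlasRegions, fwhm: float
) -> dict[str, dict[str, float]]:
    sigma = fwhm_to_sigma(fwhm)
    raw: dict[str, dict[str, float]] = {}
    for name, pts in atlas.regions.items():
        d2 = np.sum((positions[:, None, :] - pts[None, :, :]) ** 2, axis=2)  # (n_elec, n_pts)
        w = np.exp(-d2 / (2.0 * sigma**2)).sum(axis=1)
        raw[name] = dict(zip(electrode_names, w))
    return raw


def compute_weights(
    positions: np.ndarray,
    electrode_names: list[str],
    atlas: AtlasRegions,
    fwhm: float = DEFAULT_FWHM_MM,
    density_by_subject: dict[str, list[float]] | None = None,
    density_threshold: float = DENSITY_THRESHOLD,
) -> ProjectionWeights:
    """Gaussian electrode-to-region weights with density-based retention.

    ``positions`` must already be mirrored into the left hemisphere.  When
    ``density_by_subject`` is given (region -> list of per-subject densities),
    retention uses the subject-averaged density; otherwise this subject's own
    density is used.  Retained regions' weights are normalised to sum to 1
    across electrodes.
    """
    if not atlas.regions:
        raise ValueError("empty atlas")
    positions = np.asarray(positions, dtype=float)
    raw = _raw_weights(positions, electrode_names, atlas, fwhm)
    density = {name: float(sum(w.values())) for name, w in raw.items()}
    if density_by_subject is not None:
        mean_density = {name: float(np.mean(v)) for name, v in density_by_subject.items()}
    else:
        mean_density = density
    retained = [name for name in atlas.names if mean_density.get(name, 0.0) > density_threshold]
    weights: dict[str, dict[str, float]] = {}
    for name in retained:
        total = density[name]
        if total <= 0:
            weights[name] = {e: 0.0 for e in electrode_names}
        else:
            weights[name] = {e: w / total for e, w in raw[name].items()}
    return ProjectionWeights(weights=weights, density=density, retained=retained)


def project_power(power_by_electrode: dict[str, float | np.ndarray], weights: ProjectionWeights):
    """Weighted average of electrode-level power for every retained region.

    Accepts scalar band powers or arrays (e.g. whole time–frequency planes);
    projection is linear in the power values.
    """
    out = {}
    for region in weights.retained:
        w = weights.weights[region]
        missing = [e for e in w if e not in power_by_electrode]
        if missing:
            raise KeyError(f"electrodes missing from power table: {missing}")
        acc = None
        for e, we in w.items():
            term = we * np.asarray(power_by_electrode[e], dtype=float)
            acc = term if acc is None else acc + term
        out[region] = float(acc) if np.ndim(acc) == 0 else acc
    return out
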