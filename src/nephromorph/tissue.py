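"""Synthetic kidney-cortex sections with known ground truth.

A section is a discrete raster (default 512x512 cells at 2 um/cell) in
which every cell carries one of six compartment labels: interstitium,
blood vessel, intact tubule, atrophic tubule, patent glomerulus or
globally sclerotic glomerulus.  Two generators are provided:

``direct2d``
    Glomerular discs are placed first (their realized area fractions hit
    the requested fractions exactly, the last disc being trimmed), then
    the remaining cells are filled by a blocky random field so that the
    expected fraction of every compartment equals the requested one by
    construction.  This mode exists so that exhaustive-count oracles for
    the stereology estimators are exact.

``sphere3d``
    Glomeruli are a 3D Poisson process of spheres of intensity
    ``glomerular_number_density`` sectioned by the plane z = 0, so the
    classical stereological identity E[N_A] = N_V * E[diameter] holds in
    expectation and the profile-area distribution is the true
    sphere-section distribution (E[profile area] = pi d^2 / 6 for
    monodisperse spheres).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "COMPARTMENTS",
    "FRACTION_COLUMNS",
    "LABEL_CODES",
    "TissueParams",
    "LabeledSection",
    "generate_tissue_section",
]

# canonical compartment order used throughout the package
COMPARTMENTS = (
    "interstitium",
    "blood_vessel",
    "intact_tubule",
    "atrophic_tubule",
    "patent_glomerulus",
    "sclerotic_glomerulus",
)
# matching fractional-area abbreviations
FRACTION_COLUMNS = ("FIA", "FBVA", "FITA", "FATA", "FPGA", "FSGA")
# integer label codes, 1-based so 0 can mean "no glomerulus" in the id grid
LABEL_CODES = {name: i + 1 for i, name in enumerate(COMPARTMENTS)}
_PATENT = LABEL_CODES["patent_glomerulus"]
_SCLEROTIC = LABEL_CODES["sclerotic_glomerulus"]
_TISSUE_LABELS = np.array([1, 2, 3, 4], dtype=np.int8)  # non-glomerular codes


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth parameters of a synthetic cortical section.

    compartment_fractions are ordered as :data:`COMPARTMENTS` and must
    sum to 1.  ``glomerular_number_density`` is per mm^3; diameters are
    in um; ``section_side`` and ``resolution`` are in um and the
    resolution must divide the side evenly.
    """

    compartment_fractions: tuple[float, ...] = (0.25, 0.05, 0.55, 0.08, 0.05, 0.02)
    glomerular_number_density: float = 30.0
    tuft_diameter_mean: float = 140.0
    tuft_diameter_cv: float = 0.0
    sclerotic_fraction: float = 0.15
    section_side: float = 1024.0
    resolution: float = 2.0

    def __post_init__(self) -> None:
        fr = np.asarray(self.compartment_fractions, dtype=float)
        if fr.shape != (6,):
            raise InvalidParameterError("six compartment fractions are required")
        if np.any(fr < 0) or np.any(fr > 1):
            raise InvalidParameterError("compartment fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"compartment fractions must sum to 1, got {fr.sum():.12f}"
            )
        if not 0 <= self.sclerotic_fraction <= 1:
            raise InvalidParameterError("sclerotic_fraction must lie in [0, 1]")
        if self.sclerotic_fraction == 0 and fr[5] > 0:
            raise InvalidParameterError(
                "sclerotic_fraction = 0 is inconsistent with a positive "
                "sclerotic-glomerulus area fraction"
            )
        if self.tuft_diameter_mean <= 0 or self.glomerular_number_density < 0:
            raise InvalidParameterError("diameters and densities must be positive")
        if self.tuft_diameter_cv < 0:
            raise InvalidParameterError("tuft_diameter_cv must be nonnegative")
        n = self.section_side / self.resolution
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise InvalidParameterError(
                "resolution must divide section_side into a whole number of cells"
            )

    @property
    def n_cells_side(self) -> int:
        return int(round(self.section_side / self.resolution))

    def fractions_dict(self) -> dict[str, float]:
        return dict(zip(FRACTION_COLUMNS, self.compartment_fractions))


@dataclass
class LabeledSection:
    """A labeled 2D section plus per-glomerulus identity and patency."""

    label_grid: np.ndarray            # int8, codes 1..6
    glomerulus_id_grid: np.ndarray    # int32, 0 = no glomerulus
    patency_flags: dict[int, bool]
    resolution: float                 # um per cell
    truth: TissueParams
    profile_areas: dict[int, list[float]] = field(default_factory=dict)

    @property
    def cortical_area(self) -> float:
        """Section area in mm^2 (cell count times cell area)."""
        return self.label_grid.size * (self.resolution ** 2) * 1e-6

    def observed_fractions(self) -> dict[str, float]:
        """Exhaustive per-cell label count, as fractions; sums to 1 exactly."""
        n = self.label_grid.size
        counts = np.bincount(self.label_grid.ravel(), minlength=7)[1:7]
        return dict(zip(FRACTION_COLUMNS, counts / n))

    def check_congruence(self) -> bool:
        """Glomerular labels iff glomerulus id > 0."""
        is_glom = (self.label_grid == _PATENT) | (self.label_grid == _SCLEROTIC)
        return bool(np.array_equal(is_glom, self.glomerulus_id_grid > 0))

    # -- serialization: integer-matrix text files + JSON sidecar ---------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path.with_suffix(".labels.txt"), self.label_grid, fmt="%d")
        np.savetxt(path.with_suffix(".glomids.txt"), self.glomerulus_id_grid, fmt="%d")
        meta = {
            "resolution": self.resolution,
            "patency_flags": {str(k): bool(v) for k, v in self.patency_flags.items()},
            "profile_areas": {str(k): v for k, v in self.profile_areas.items()},
            "truth": {
                "compartment_fractions": list(self.truth.compartment_fractions),
                "glomerular_number_density": self.truth.glomerular_number_density,
                "tuft_diameter_mean": self.truth.tuft_diameter_mean,
                "tuft_diameter_cv": self.truth.tuft_diameter_cv,
                "sclerotic_fraction": self.truth.sclerotic_fraction,
                "section_side": self.truth.section_side,
                "resolution": self.truth.resolution,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LabeledSection":
        path = Path(path)
        labels = np.loadtxt(path.with_suffix(".labels.txt"), dtype=np.int8)
        ids = np.loadtxt(path.with_suffix(".glomids.txt"), dtype=np.int32)
        meta = json.loads(path.with_suffix(".json").read_text())
        truth = TissueParams(
            compartment_fractions=tuple(meta["truth"]["compartment_fractions"]),
            glomerular_number_density=meta["truth"]["glomerular_number_density"],
            tuft_diameter_mean=meta["truth"]["tuft_diameter_mean"],
            tuft_diameter_cv=meta["truth"]["tuft_diameter_cv"],
            sclerotic_fraction=meta["truth"]["sclerotic_fraction"],
            section_side=meta["truth"]["section_side"],
            resolution=meta["truth"]["resolution"],
        )
        return cls(
            label_grid=np.atleast_2d(labels),
            glomerulus_id_grid=np.atleast_2d(ids),
            patency_flags={int(k): v for k, v in meta["patency_flags"].items()},
            resolution=float(meta["resolution"]),
            truth=truth,
            profile_areas={int(k): list(v) for k, v in meta["profile_areas"].items()},
        )


def _disc_cells(n: int, cx: float, cy: float, radius: float, wrap: bool = False):
    """Cell indices inside a disc, with squared centre distances.

    With ``wrap`` the disc lives on a torus (used by direct2d so the
    glomerular field is stationary — no edge depletion); otherwise it is
    clipped at the section boundary (sphere3d, like a real section).
    """
    x0 = int(np.floor(cx - radius)) - 1
    x1 = int(np.ceil(cx + radius)) + 2
    y0 = int(np.floor(cy - radius)) - 1
    y1 = int(np.ceil(cy + radius)) + 2
    if not wrap:
        x0, x1 = max(x0, 0), min(x1, n)
        y0, y1 = max(y0, 0), min(y1, n)
        if x0 >= x1 or y0 >= y1:
            return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2
    inside = d2 <= radius ** 2
    yy, xx, d2 = yy[inside], xx[inside], d2[inside]
    if wrap:
        yy, xx = yy % n, xx % n
    return yy, xx, d2


def _draw_diameters(rng: np.random.Generator, k: int, mean: float, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.full(k, mean)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=k)


def _blocky_fill(rng, n: int, probs: np.ndarray, block: int = 16) -> np.ndarray:
    """Random non-glomerular label field with block-level patchiness."""
    nb = int(np.ceil(n / block))
    blocks = rng.choice(_TISSUE_LABELS, size=(nb, nb), p=probs)
    return np.kron(blocks, np.ones((block, block), dtype=np.int8))[:n, :n]


def _generate_direct2d(params: TissueParams, rng) -> LabeledSection:
    n = params.n_cells_side
    total = n * n
    fr = np.asarray(params.compartment_fractions)
    targets = {
        _PATENT: int(round(fr[4] * total)),
        _SCLEROTIC: int(round(fr[5] * total)),
    }

    labels = np.zeros((n, n), dtype=np.int8)
    ids = np.zeros((n, n), dtype=np.int32)
    patency: dict[int, bool] = {}
    profiles: dict[int, list[float]] = {}
    next_id = 1
    cell_area = params.resolution ** 2

    for code, patent in ((_PATENT, True), (_SCLEROTIC, False)):
        placed = 0
        target = targets[code]
        tries = 0
        while placed < target and tries < 10_000:
            tries += 1
            d = _draw_diameters(rng, 1, params.tuft_diameter_mean, params.tuft_diameter_cv)[0]
            radius = d / 2.0 / params.resolution
            cx, cy = rng.uniform(0, n, size=2)
            yy, xx, d2 = _disc_cells(n, cx, cy, radius, wrap=True)
            free = ids[yy, xx] == 0
            if not free.all() or free.sum() == 0:
                continue  # reject overlap with an existing glomerulus
            remaining = target - placed
            if len(yy) > remaining:
                # trim the last disc: keep the cells closest to its centre
                order = np.argsort(d2)[:remaining]
                yy, xx = yy[order], xx[order]
            labels[yy, xx] = code
            ids[yy, xx] = next_id
            patency[next_id] = patent
            profiles[next_id] = [float(len(yy) * cell_area)]
            next_id += 1
            placed += len(yy)

    # fill the remaining cells with a patchy random field whose per-cell
    # label distribution is the renormalized non-glomerular fractions
    tissue_probs = fr[:4] / fr[:4].sum() if fr[:4].sum() > 0 else np.full(4, 0.25)
    background = _blocky_fill(rng, n, tissue_probs)
    mask = labels == 0
    labels[mask] = background[mask]

    return LabeledSection(labels, ids, patency, params.resolution, params, profiles)


def _generate_sphere3d(params: TissueParams, rng) -> LabeledSection:
    n = params.n_cells_side
    side = params.section_side  # um
    d_mean = params.tuft_diameter_mean
    cv = params.tuft_diameter_cv
    # z-slab thick enough to contain every sphere that can touch z = 0
    d_max = d_mean if cv <= 0 else d_mean * (1 + 6 * cv)
    half = d_max / 2.0
    nv_um3 = params.glomerular_number_density * 1e-9  # per um^3
    volume = side * side * (2 * half)
    k = rng.poisson(nv_um3 * volume)

    xs = rng.uniform(0, side, k)
    ys = rng.uniform(0, side, k)
    zs = rng.uniform(-half, half, k)
    ds = _draw_diameters(rng, k, d_mean, cv)
    cut = np.abs(zs) < ds / 2.0
    xs, ys, zs, ds = xs[cut], ys[cut], zs[cut], ds[cut]
    rho = np.sqrt((ds / 2.0) ** 2 - zs ** 2)  # profile radii, um

    labels = np.zeros((n, n), dtype=np.int8)
    ids = np.zeros((n, n), dtype=np.int32)
    patency: dict[int, bool] = {}
    profiles: dict[int, list[float]] = {}
    res = params.resolution
    next_id = 1
    for x, y, r in zip(xs, ys, rho):
        # unbiased counting rule: only profiles whose centre lies in the
        # window are drawn, so the expected count is N_V * E[d] * area
        cx, cy = x / res, y / res
        got = _disc_cells(n, cx, cy, r / res)
        patent = bool(rng.random() >= params.sclerotic_fraction)
        code = _PATENT if patent else _SCLEROTIC
        if got is not None:
            yy, xx, _ = got
            free = ids[yy, xx] == 0
            yy, xx = yy[free], xx[free]
            labels[yy, xx] = code
            ids[yy, xx] = next_id
        # guarantee at least the centre cell so the profile is countable
        iy, ix = min(int(cy), n - 1), min(int(cx), n - 1)
        if ids[iy, ix] == 0 or ids[iy, ix] == next_id:
            labels[iy, ix] = code
            ids[iy, ix] = next_id
        patency[next_id] = patent
        profiles[next_id] = [float(np.pi * r ** 2)]
        next_id += 1

    fr = np.asarray(params.compartment_fractions)
    tissue_probs = fr[:4] / fr[:4].sum() if fr[:4].sum() > 0 else np.full(4, 0.25)
    background = _blocky_fill(rng, n, tissue_probs)
    mask = labels == 0
    labels[mask] = background[mask]
    return LabeledSection(labels, ids, patency, params.resolution, params, profiles)


def generate_tissue_section(
    params: TissueParams,
    mode: str = "direct2d",
    seed: int | np.random.Generator | None = None,
) -> LabeledSection:
    """Generate one labeled cortical section.

    Parameters
    ----------
    params : TissueParams
        Ground truth; validated on construction.
    mode : {"direct2d", "sphere3d"}
        ``direct2d`` honours the six compartment fractions exactly in
        expectation; ``sphere3d`` sections a 3D Poisson sphere process so
        stereological identities hold.
    seed : int, Generator or None
        Source of randomness; identical seeds give identical sections.
    """
    rng = np.random.default_rng(seed)
    if mode == "direct2d":
        return _generate_direct2d(params, rng)
    if mode == "sphere3d":
        return _generate_sphere3d(params, rng)
    raise InvalidParameterError(f"unknown section mode: {mode!r}")
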