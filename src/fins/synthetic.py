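"""Synthetic multi-channel fluorescence fields with known ground truth.

Emulates the image properties the counting pipeline must cope with: fields
of non-overlapping elliptical nuclei of heterogeneous size (from condensed
mitotic to large polyploid), a uniform autofluorescence background with
additive Gaussian noise and impulse ("hot pixel") speckles, dim cell
detritus, nuclei cropped by the image border, and per-nucleus punctate
marker foci placed strictly inside a known subset of nuclei.  Every fixture
carries its ground truth (nucleus count, label image, per-marker positive
ids), so segmentation and counting can be scored exactly.

Not simulated: optical point-spread, vignetting, chromatic shift, or
overlapping post-mitotic nuclei (merging touching nuclei is a known
limitation of two-phase segmentation, not something to score against).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from fins.image_io import ChannelImage


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement fails within the attempt budget."""


@dataclass(frozen=True)
class MarkerSpec:
    """One marker channel: which fraction of nuclei is positive and how its foci look.

    Focus intensity defaults to 0.8 against a 0.05 background so the marker
    Otsu threshold lands far above the 0.1 floor; a dim preset (intensity
    below the floor) exercises the floor path.
    """

    name: str
    positive_fraction: float
    foci_per_nucleus: int = 3
    focus_intensity: float = 0.8
    focus_radius: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.foci_per_nucleus < 1:
            raise ValueError("foci_per_nucleus must be >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic field.

    ``taper_px`` is the width of the cosine intensity taper at the nuclear
    rim; 0 gives piecewise-constant (hard-edged) nuclei, used for the
    noiseless oracle-equivalence checks.  ``border_fraction`` of the nuclei
    are centred within one radius of the image border and therefore cropped.
    Speckle impulses affect the counterstain channel only (set to
    ``speckle_intensity``), modelling isolated hot pixels the TV term should
    remove but plain thresholding counts.

    Marker channels are dark outside their foci (``marker_background``) and
    carry ``marker_noise_factor * noise_sigma`` of additive noise: detector
    noise in fluorescence is dominated by shot noise, which scales with the
    collected signal, so a channel that is black outside sparse puncta has a
    much lower noise floor than the uniformly stained counterstain.
    """

    height: int = 512
    width: int = 512
    n_nuclei: int = 30
    radius_range: tuple[float, float] = (6.0, 16.0)
    intensity_nucleus: float = 0.75
    background: float = 0.05
    noise_sigma: float = 0.02
    speckle_rate: float = 2e-4
    speckle_intensity: float = 0.5
    marker_background: float = 0.02
    marker_noise_factor: float = 0.25
    n_detritus: int = 3
    detritus_intensity: float = 0.18
    border_fraction: float = 0.1
    taper_px: float = 2.0
    marker_specs: tuple[MarkerSpec, ...] = (
        MarkerSpec("Ki67", positive_fraction=0.4, foci_per_nucleus=3, focus_radius=2.5),
        MarkerSpec("gH2AX", positive_fraction=0.6, foci_per_nucleus=5, focus_radius=1.5),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("field must be at least 1x1")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise ValueError("radius_range must satisfy 0 < min <= max")
        for rate in (self.speckle_rate, self.border_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not 0.0 < self.intensity_nucleus <= 1.0:
            raise ValueError("intensity_nucleus must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth of one fixture, consistent with the rendered pixels."""

    n_nuclei: int
    centers: np.ndarray  # (n, 2) row, col
    axes: np.ndarray  # (n, 3) semi-major, semi-minor, angle
    positive_ids: dict[str, frozenset[int]]
    label_image: np.ndarray

    def __post_init__(self) -> None:
        for name, ids in self.positive_ids.items():
            if ids and (min(ids) < 1 or max(ids) > self.n_nuclei):
                raise ValueError(f"{name}: positive ids outside 1..{self.n_nuclei}")


def _elliptical_radius(shape: tuple[int, int], center: np.ndarray, a: float, b: float, theta: float) -> np.ndarray:
    """Normalised elliptical radius (1 on the boundary) over a bounding window."""
    r0, c0 = center
    pad = int(np.ceil(max(a, b))) + 2
    r_lo, r_hi = max(0, int(r0) - pad), min(shape[0], int(r0) + pad + 1)
    c_lo, c_hi = max(0, int(c0) - pad), min(shape[1], int(c0) + pad + 1)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    dr, dc = rr - r0, cc - c0
    ct, st = np.cos(theta), np.sin(theta)
    major = dr * ct + dc * st
    minor = -dr * st + dc * ct
    rho = np.sqrt((major / a) ** 2 + (minor / b) ** 2)
    return rho, (slice(r_lo, r_hi), slice(c_lo, c_hi))


def _profile(rho: np.ndarray, taper_frac: float) -> np.ndarray:
    """Unit plateau with a cosine taper to zero over [1 - taper_frac, 1]."""
    if taper_frac <= 0:
        return (rho <= 1.0).astype(float)
    out = np.zeros_like(rho)
    out[rho <= 1.0 - taper_frac] = 1.0
    ramp = (rho > 1.0 - taper_frac) & (rho <= 1.0)
    out[ramp] = 0.5 * (1.0 + np.cos(np.pi * (rho[ramp] - (1.0 - taper_frac)) / taper_frac))
    return out


def _place_nuclei(spec: FixtureSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping ellipse centres and axes."""
    gap = 4.0  # minimum clearance between nuclear supports, px
    lo, hi = spec.radius_range
    mean_area = np.pi * ((lo + hi) / 2) ** 2
    if spec.n_nuclei * mean_area > 0.4 * spec.height * spec.width:
        raise PlacementError("total nucleus area exceeds 40% of the field; placement infeasible")
    n_border = int(round(spec.border_fraction * spec.n_nuclei))
    centers: list[np.ndarray] = []
    axes: list[tuple[float, float, float]] = []
    max_attempts = 500 * max(spec.n_nuclei, 1)
    attempts = 0
    while len(centers) < spec.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(f"placement failed after {max_attempts} attempts")
        r = rng.uniform(lo, hi)
        ratio = rng.uniform(1.0, 1.4)
        a, b = r, r / ratio
        theta = rng.uniform(0, np.pi)
        is_border = len(centers) < n_border
        if is_border:
            # centre within one radius of a randomly chosen edge
            edge = rng.integers(4)
            offset = rng.uniform(0, a)
            along_r = rng.uniform(0, spec.height)
            along_c = rng.uniform(0, spec.width)
            center = {
                0: np.array([offset, along_c]),
                1: np.array([spec.height - 1 - offset, along_c]),
                2: np.array([along_r, offset]),
                3: np.array([along_r, spec.width - 1 - offset]),
            }[int(edge)]
        else:
            margin = a + gap
            if spec.height <= 2 * margin or spec.width <= 2 * margin:
                continue
            center = np.array([rng.uniform(margin, spec.height - margin), rng.uniform(margin, spec.width - margin)])
        ok = all(
            np.linalg.norm(center - c) > a + ax[0] + gap for c, ax in zip(centers, axes)
        )
        if ok:
            centers.append(center)
            axes.append((a, b, theta))
    return np.asarray(centers).reshape(spec.n_nuclei, 2), np.asarray(axes).reshape(spec.n_nuclei, 3)


def generate_fixture(spec: FixtureSpec) -> tuple[list[ChannelImage], FixtureTruth]:
    """Render one synthetic acquisition and its ground truth.

    Returns channels in pipeline order (counterstain first, then markers in
    ``spec.marker_specs`` order).  The same spec (including seed) always
    produces bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    centers, axes = _place_nuclei(spec, rng)
    dapi = np.full(shape, spec.background, dtype=float)
    label_image = np.zeros(shape, dtype=np.int32)
    for i in range(spec.n_nuclei):
        a, b, theta = axes[i]
        rho, window = _elliptical_radius(shape, centers[i], a, b, theta)
        taper_frac = min(spec.taper_px / min(a, b), 0.9) if spec.taper_px > 0 else 0.0
        prof = _profile(rho, taper_frac)
        dapi[window] = np.maximum(dapi[window], spec.background + (spec.intensity_nucleus - spec.background) * prof)
        label_image[window][rho <= 1.0] = i + 1
    # dim detritus: small odd-shaped blobs below the nuclear intensity scale
    for _ in range(spec.n_detritus):
        r = rng.uniform(1.5, 4.0)
        ratio = rng.uniform(1.0, 3.0)
        theta = rng.uniform(0, np.pi)
        center = np.array([rng.uniform(0, spec.height), rng.uniform(0, spec.width)])
        if any(np.linalg.norm(center - c) < ax[0] + r + 4.0 for c, ax in zip(centers, axes)):
            continue
        rho, window = _elliptical_radius(shape, center, r, r / ratio, theta)
        dapi[window] = np.maximum(dapi[window], spec.background + (spec.detritus_intensity - spec.background) * (rho <= 1.0))

    # marker channels: punctate foci strictly inside the positive nuclei
    positive_ids: dict[str, frozenset[int]] = {}
    marker_fields: list[np.ndarray] = []
    for mspec in spec.marker_specs:
        n_pos = int(round(mspec.positive_fraction * spec.n_nuclei))
        chosen = rng.choice(spec.n_nuclei, size=n_pos, replace=False) + 1 if n_pos else np.array([], dtype=int)
        positive_ids[mspec.name] = frozenset(int(i) for i in chosen)
        zm = np.full(shape, spec.marker_background, dtype=float)
        for nucleus_id in sorted(chosen):
            a, b, theta = axes[nucleus_id - 1]
            center = centers[nucleus_id - 1]
            planted = 0
            for _ in range(mspec.foci_per_nucleus):
                # focus centre at elliptical radius <= 0.5 keeps the focus
                # peak strictly inside the nuclear region after tapering
                fc = None
                for _ in range(50):
                    rho_f = rng.uniform(0, 0.5)
                    phi = rng.uniform(0, 2 * np.pi)
                    ct, st = np.cos(theta), np.sin(theta)
                    offset = rho_f * np.array([a * np.cos(phi) * ct - b * np.sin(phi) * st,
                                               a * np.cos(phi) * st + b * np.sin(phi) * ct])
                    cand = center + offset
                    if 0 <= cand[0] < spec.height and 0 <= cand[1] < spec.width:
                        fc = cand
                        break
                if fc is None:
                    continue
                rho, window = _elliptical_radius(shape, fc, mspec.focus_radius, mspec.focus_radius, 0.0)
                prof = _profile(rho, min(1.0 / mspec.focus_radius, 0.9))
                zm[window] = np.maximum(zm[window], spec.marker_background + (mspec.focus_intensity - spec.marker_background) * prof)
                planted += 1
            if planted == 0:
                # cropped nucleus: plant one focus at the (always in-image) centre
                rho, window = _elliptical_radius(shape, center, mspec.focus_radius, mspec.focus_radius, 0.0)
                prof = _profile(rho, min(1.0 / mspec.focus_radius, 0.9))
                zm[window] = np.maximum(zm[window], spec.marker_background + (mspec.focus_intensity - spec.marker_background) * prof)
        marker_fields.append(zm)

    if spec.noise_sigma > 0:
        dapi = dapi + rng.normal(0.0, spec.noise_sigma, shape)
        marker_fields = [m + rng.normal(0.0, spec.marker_noise_factor * spec.noise_sigma, shape) for m in marker_fields]
    if spec.speckle_rate > 0:
        speckles = rng.random(shape) < spec.speckle_rate
        dapi[speckles] = spec.speckle_intensity
    dapi = np.clip(dapi, 0.0, 1.0)
    marker_fields = [np.clip(m, 0.0, 1.0) for m in marker_fields]

    channels = [ChannelImage(dapi, "counterstain", "DAPI")] + [
        ChannelImage(zm, "marker", mspec.name) for zm, mspec in zip(marker_fields, spec.marker_specs)
    ]
    truth = FixtureTruth(
        n_nuclei=spec.n_nuclei,
        centers=centers,
        axes=axes,
        positive_ids=positive_ids,
        label_image=label_image,
    )
    return channels, truth


def sweep_fixtures(
    base: FixtureSpec, noise_levels: list[float], reps: int = 1
) -> list[tuple[FixtureSpec, list[ChannelImage], FixtureTruth]]:
    """Generate ``reps`` fixtures per noise level with derived, distinct seeds."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    out = []
    index = 0
    for sigma in noise_levels:
        for _ in range(reps):
            spec = dataclasses.replace(base, noise_sigma=sigma, seed=(base.seed + index) % (2**31 - 1))
            channels, truth = generate_fixture(spec)
            out.append((spec, channels, truth))
            index += 1
    return out


def write_fixture(channels: list[ChannelImage], truth: FixtureTruth, path: str | Path) -> Path:
    """Write a fixture as a multi-plane 16-bit OME-TIFF with a JSON truth sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    planes = np.stack([np.round(ch.z * 65535).astype(np.uint16) for ch in channels])
    tifffile.imwrite(path, planes, photometric="minisblack", metadata={"axes": "CYX"})
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    sidecar.write_text(
        json.dumps(
            {
                "n_nuclei": truth.n_nuclei,
                "positive_ids": {k: sorted(v) for k, v in truth.positive_ids.items()},
                "channel_names": [ch.name for ch in channels],
            },
            indent=2,
        )
    )
    return path
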