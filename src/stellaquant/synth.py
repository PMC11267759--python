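"""Seeded generators for every input the analysis modules consume.

Each generator is a pure function of its parameters and an integer seed:
regenerating with the same arguments reproduces byte-identical arrays. Every
call returns the synthetic object together with a :class:`GroundTruth`
sidecar listing all planted entities, so downstream stages can be tested by
parameter recovery rather than by eye.

All generators expose a noise-free mode (``snr=inf`` / ``noise_sd=0`` /
``sd=0``) so exact tests remain possible.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import GroundTruth, PackingError, RamanScan, VoxelVolume

# Refractive-index plateaus: culture medium, cytoplasm, and lipid droplets.
# Lipids sit well above cytoplasm, which is what makes droplets easy to
# identify in holotomography.
RI_BACKGROUND = 1.337
RI_CELL = 1.350
RI_DROPLET = 1.380

_MAX_PLACEMENT_ATTEMPTS = 10_000


def _voxel_centers(shape, voxel_size):
    """Physical voxel-center coordinate arrays (open mesh), in µm."""
    return [
        (np.arange(n, dtype=float) + 0.5) * d
        for n, d in zip(shape, voxel_size)
    ]


def gen_ht_volume(
    shape=(64, 64, 64),
    voxel_size=(0.25, 0.25, 0.25),
    n_droplets=20,
    radius_range=(0.5, 2.0),
    snr=5.0,
    seed=0,
    cell_axes_fraction=(0.84, 0.84, 0.84),
    max_attempts=_MAX_PLACEMENT_ATTEMPTS,
):
    """Synthesize a holotomography-like refractive-index volume.

    One smooth ellipsoidal cell body of raised refractive index sits on a
    flat background; ``n_droplets`` non-overlapping bright spheres are packed
    wholly inside the cell. Gaussian noise of standard deviation
    ``(RI_CELL - RI_BACKGROUND) / snr`` is added (``snr=inf`` → noise-free).

    Parameters
    ----------
    shape : tuple
        Volume shape (nz, ny, nx) in voxels.
    voxel_size : tuple
        (dz, dy, dx) in µm.
    n_droplets : int
        Number of lipid droplets to plant.
    radius_range : tuple
        (min, max) droplet radius in µm; must lie within [0.3, 5] µm.
    snr : float
        Cell-to-background contrast divided by the noise standard deviation.
    cell_axes_fraction : tuple
        Ellipsoid semi-axes as a fraction of each physical half-extent.

    Returns
    -------
    (VoxelVolume, GroundTruth)
        Ground truth records droplet centers (µm), radii (µm), the exact
        cell mask, and the closed-form total planted lipid volume.
    """
    rmin, rmax = float(radius_range[0]), float(radius_range[1])
    if not (0.3 <= rmin <= rmax <= 5.0):
        raise ValueError(f"radius_range must lie within [0.3, 5] µm, got {radius_range}")
    if n_droplets < 0:
        raise ValueError("n_droplets must be non-negative")

    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in shape)
    zc, yc, xc = _voxel_centers(shape, voxel_size)
    extent = [n * d for n, d in zip(shape, voxel_size)]
    center = [e / 2.0 for e in extent]
    semi = [f * e / 2.0 for f, e in zip(cell_axes_fraction, extent)]

    # Normalized ellipsoidal radius on the voxel grid.
    rr = np.sqrt(
        ((zc - center[0]) / semi[0])[:, None, None] ** 2
        + ((yc - center[1]) / semi[1])[None, :, None] ** 2
        + ((xc - center[2]) / semi[2])[None, None, :] ** 2
    )
    cell_mask = rr <= 1.0
    # Soft shoulder (~2 voxels wide) so the body is smooth, not a step.
    edge = 2.0 * min(voxel_size) / min(semi)
    body = 1.0 / (1.0 + np.exp((rr - 1.0) / (edge / 4.0)))
    data = RI_BACKGROUND + (RI_CELL - RI_BACKGROUND) * body

    # Rejection-sample droplet centers: each sphere must lie wholly inside
    # the ellipsoid and must not overlap previously placed droplets. All
    # radii are drawn up front and placed largest-first, which packs far
    # more reliably than placing in draw order.
    min_semi = min(semi)
    radii_all = np.sort(rng.uniform(rmin, rmax, size=n_droplets))[::-1]
    centers: list[np.ndarray] = []
    radii: list[float] = []
    attempts = 0
    for r in radii_all:
        placed = False
        while not placed:
            if attempts >= max_attempts:
                raise PackingError(
                    f"could not place droplet {len(radii) + 1}/{n_droplets} "
                    f"after {max_attempts} attempts; reduce n_droplets or radii"
                )
            attempts += 1
            pos = np.array([rng.uniform(r, e - r) for e in extent])
            # Wholly inside: shrink the ellipsoid by r along its shortest axis.
            rho = math.sqrt(sum(((p - c) / s) ** 2 for p, c, s in zip(pos, center, semi)))
            if rho > 1.0 - r / min_semi:
                continue
            if any(np.linalg.norm(pos - c0) < r + r0 for c0, r0 in zip(centers, radii)):
                continue
            centers.append(pos)
            radii.append(float(r))
            placed = True

    for pos, r in zip(centers, radii):
        d2 = (
            ((zc - pos[0]) ** 2)[:, None, None]
            + ((yc - pos[1]) ** 2)[None, :, None]
            + ((xc - pos[2]) ** 2)[None, None, :]
        )
        data = np.where(d2 <= r * r, RI_DROPLET, data)

    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive (or inf for noise-free)")
        data = data + rng.normal(0.0, (RI_CELL - RI_BACKGROUND) / snr, size=shape)

    total_lipid = float(sum(4.0 / 3.0 * math.pi * r**3 for r in radii))
    gt = GroundTruth(
        kind="ht_volume",
        objects={
            "droplet_centers_um": np.array(centers).reshape(-1, 3),
            "droplet_radii_um": np.array(radii, dtype=float),
            "cell_mask": cell_mask,
            "total_lipid_volume_um3": total_lipid,
            "cell_volume_um3": float(cell_mask.sum()) * math.prod(voxel_size),
            "levels": {"background": RI_BACKGROUND, "cell": RI_CELL, "droplet": RI_DROPLET},
        },
        seed=int(seed),
        params={
            "shape": shape, "voxel_size": tuple(voxel_size),
            "n_droplets": int(n_droplets), "radius_range": (rmin, rmax),
            "snr": float(snr), "cell_axes_fraction": tuple(cell_axes_fraction),
        },
    )
    return VoxelVolume(data, tuple(voxel_size)), gt


def gen_mito_volume(
    shape=(32, 64, 64),
    voxel_size=(0.2, 0.2, 0.2),
    n_components=5,
    tube_radius=0.3,
    seed=0,
    steps_per_tube=40,
    noise_sd=0.0,
    split_tubes=False,
    in_plane=True,
    max_attempts=_MAX_PLACEMENT_ATTEMPTS,
):
    """Synthesize a MitoTracker-like stack of tubular mitochondria.

    Each component is a random-walk tube (unit steps of at most one voxel
    per axis, dilated to ``tube_radius``), so it is 26-connected internally;
    components are separated by at least 2 voxels. By default each tube
    meanders within one z-plane (``in_plane=True``), mimicking the flat
    mitochondrial network of an adherent cell; ``in_plane=False`` lets
    tubes drift in z as well. ``split_tubes=True`` cuts every tube in the
    middle (3-voxel gap), doubling the component count at nearly constant
    total signal — the fragmentation phenotype.

    Returns ``(VoxelVolume, GroundTruth)``; ground truth stores the voxel
    list of every component.
    """
    if n_components < 0:
        raise ValueError("n_components must be non-negative")
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in shape)
    rad_vox = [tube_radius / d for d in voxel_size]

    occupied = np.zeros(shape, dtype=bool)        # all placed tubes
    forbidden = np.zeros(shape, dtype=bool)       # tubes dilated by the 2-voxel gap
    components: list[np.ndarray] = []
    n_tubes = 0
    attempts = 0
    while n_tubes < n_components:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place mitochondrion {n_tubes + 1}/"
                f"{n_components} after {max_attempts} attempts"
            )
        attempts += 1
        margin = [int(math.ceil(r)) + 1 for r in rad_vox]
        if any(2 * m + 2 >= n for m, n in zip(margin, shape)):
            raise ValueError("shape too small for the requested tube radius")
        start = np.array([rng.integers(m, n - m) for m, n in zip(margin, shape)])
        path = [start]
        pos = start.astype(float)
        drift = rng.normal(size=3)
        if in_plane:
            drift[0] = 0.0
        drift /= max(np.linalg.norm(drift), 1e-9)
        for _ in range(steps_per_tube):
            kick = 0.4 * rng.normal(size=3)
            if in_plane:
                kick[0] = 0.0
            drift = drift + kick
            drift /= max(np.linalg.norm(drift), 1e-9)
            pos = pos + drift
            ivox = np.clip(np.round(pos).astype(int), margin, np.array(shape) - 1 - np.array(margin))
            pos = np.clip(pos, margin, np.array(shape) - 1 - np.array(margin))
            if not np.array_equal(ivox, path[-1]):
                # keep per-slice displacement ≤ 1 voxel per axis
                step = np.clip(ivox - path[-1], -1, 1)
                path.append(path[-1] + step)
        tube = _dilate_path(np.array(path), shape, rad_vox)
        halo = _dilate_path(np.array(path), shape, [r + 2.0 for r in rad_vox])
        if (halo & forbidden).any():
            continue
        if split_tubes:
            mid = len(path) // 2
            gap = _dilate_path(np.array(path[mid - 1:mid + 2]), shape, [r + 1.0 for r in rad_vox])
            tube = tube & ~gap
            parts = _split_voxel_sets(tube)
            if len(parts) != 2:
                continue
            components.extend(parts)
        else:
            components.append(np.argwhere(tube))
        n_tubes += 1
        occupied |= tube
        forbidden |= halo

    data = np.full(shape, 10.0)
    data[occupied] = 100.0
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=shape)

    gt = GroundTruth(
        kind="mito_volume",
        objects={
            "component_voxels": components,
            "n_components": len(components),
            "binary": occupied,
        },
        seed=int(seed),
        params={
            "shape": shape, "voxel_size": tuple(voxel_size),
            "n_components": int(n_components), "tube_radius": float(tube_radius),
            "steps_per_tube": int(steps_per_tube), "noise_sd": float(noise_sd),
            "split_tubes": bool(split_tubes),
        },
    )
    return VoxelVolume(data, tuple(voxel_size)), gt


def _dilate_path(path: np.ndarray, shape, rad_vox) -> np.ndarray:
    """Voxels within an (anisotropic) radius of any path point."""
    out = np.zeros(shape, dtype=bool)
    ir = [int(math.ceil(r)) for r in rad_vox]
    offs = np.array(
        [
            (a, b, c)
            for a in range(-ir[0], ir[0] + 1)
            for b in range(-ir[1], ir[1] + 1)
            for c in range(-ir[2], ir[2] + 1)
            if (a / max(rad_vox[0], 1e-9)) ** 2
            + (b / max(rad_vox[1], 1e-9)) ** 2
            + (c / max(rad_vox[2], 1e-9)) ** 2
            <= 1.0
        ]
    )
    if offs.size == 0:
        offs = np.zeros((1, 3), dtype=int)
    pts = (path[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    pts = np.clip(pts, 0, np.array(shape) - 1)
    out[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return out


def _split_voxel_sets(binary: np.ndarray) -> list[np.ndarray]:
    from scipy import ndimage

    lab, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    return [np.argwhere(lab == i) for i in range(1, n + 1)]


def gen_raman_scan(
    n_points=40,
    n_lines=40,
    wavenumbers=None,
    va_band=(1590.0, 16.0),
    lipid_band=(2900.0, 50.0),
    rho=0.8,
    spike_rate=1e-4,
    noise_sd=0.05,
    amp_mean=1.0,
    amp_sd=0.3,
    spike_min_factor=10.0,
    spike_width=1,
    baseline_pixel_sd=0.0,
    cellular_amp_sd=0.02,
    seed=0,
):
    """Synthesize a confocal Raman large-area scan.

    Per-pixel spectrum = smooth cubic fluorescence baseline + a fixed
    cellular Raman signature (protein/CH bands outside the two analysis
    windows, so the full-range integral is dominated by cell material as in
    real spectra) + vitamin-A Gaussian band + lipid Gaussian band + white
    noise + sparse positive cosmic-ray spikes. Band amplitudes
    ``(a_VA, a_lip)`` are drawn jointly Gaussian with correlation ``rho``;
    spikes are single-channel deltas (width 2 via ``spike_width=2``) of
    amplitude at least ``spike_min_factor`` times the local signal. Spike
    placement is Poisson with ``spike_rate`` expected spikes per channel per
    pixel. ``baseline_pixel_sd`` adds per-pixel baseline scale variation (0
    by default: the study convention fits one baseline per scan on the mean
    spectrum, and a nonzero pixel scatter is a stress-test option).

    Returns ``(RamanScan, GroundTruth)``; ground truth stores per-pixel
    amplitudes, the noise-free cube, and every spike position.
    """
    if wavenumbers is None:
        wavenumbers = np.linspace(400.0, 3200.0, 1024)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if not np.all(np.diff(wavenumbers) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    for name, (c, _w) in (("va_band", va_band), ("lipid_band", lipid_band)):
        if not (wavenumbers[0] <= c <= wavenumbers[-1]):
            raise ValueError(f"{name} center {c} outside wavenumber range")
    if abs(rho) > 1:
        raise ValueError("|rho| must be ≤ 1")

    rng = np.random.default_rng(seed)
    n_pix = n_lines * n_points

    # Jointly Gaussian amplitudes with exact degenerate behaviour at |rho|=1.
    z1 = rng.normal(size=n_pix)
    z2 = rng.normal(size=n_pix)
    a_va = amp_mean + amp_sd * z1
    a_lip = amp_mean + amp_sd * (rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2)
    a_va = np.abs(a_va)
    a_lip = np.abs(a_lip)  # physical amplitudes are non-negative

    w = wavenumbers
    g_va = np.exp(-0.5 * ((w - va_band[0]) / va_band[1]) ** 2)
    g_lip = np.exp(-0.5 * ((w - lipid_band[0]) / lipid_band[1]) ** 2)
    # Fixed cellular Raman signature (phenylalanine ring breathing, amide
    # III, CH2 deformation, amide I, high-wavenumber tail) — all outside the
    # retinoid and lipid analysis windows. Its area dominates the full-range
    # integral, as cell material does in real spectra.
    cellular = np.zeros_like(w)
    for c0, width, amp in ((1004, 22, 12.0), (1260, 24, 9.0), (1450, 24, 15.0),
                           (1660, 28, 18.0), (3130, 30, 9.0)):
        cellular += amp * np.exp(-0.5 * ((w - c0) / width) ** 2)
    a_cell = 1.0 + cellular_amp_sd * rng.normal(size=n_pix)
    # Shared smooth fluorescence-like baseline with optional per-pixel scale.
    t = (w - w[0]) / (w[-1] - w[0])
    base_shape = 2.0 + 1.5 * t - 0.8 * t**2 + 0.3 * t**3
    base_scale = 1.0 + baseline_pixel_sd * rng.normal(size=n_pix)

    clean = (
        base_scale[:, None] * base_shape[None, :]
        + a_cell[:, None] * cellular[None, :]
        + a_va[:, None] * g_va[None, :]
        + a_lip[:, None] * g_lip[None, :]
    )
    cube = clean.copy()
    if noise_sd > 0:
        cube = cube + rng.normal(0.0, noise_sd, size=cube.shape)

    spikes: list[tuple[int, int, float]] = []  # (pixel, channel, amplitude)
    if spike_rate > 0:
        n_spikes = rng.poisson(spike_rate * n_pix * w.size)
        hit: set[tuple[int, int]] = set()
        for _ in range(int(n_spikes)):
            p = int(rng.integers(0, n_pix))
            ch = int(rng.integers(0, w.size))
            amp = float(spike_min_factor * max(clean[p, ch], 1.0) * rng.uniform(1.0, 3.0))
            for dc in range(spike_width):
                if ch + dc < w.size and (p, ch + dc) not in hit:
                    cube[p, ch + dc] += amp
                    spikes.append((p, ch + dc, amp))
                    hit.add((p, ch + dc))

    cube3 = cube.reshape(n_lines, n_points, w.size)
    gt = GroundTruth(
        kind="raman_scan",
        objects={
            "a_va": a_va.reshape(n_lines, n_points),
            "a_lip": a_lip.reshape(n_lines, n_points),
            "rho": float(rho),
            "spikes": spikes,
            "clean_cube": clean.reshape(n_lines, n_points, w.size),
            "baseline_cube": (base_scale[:, None] * base_shape[None, :]).reshape(
                n_lines, n_points, w.size
            ),
            "va_band": tuple(va_band),
            "lipid_band": tuple(lipid_band),
        },
        seed=int(seed),
        params={
            "n_points": int(n_points), "n_lines": int(n_lines),
            "va_band": tuple(va_band), "lipid_band": tuple(lipid_band),
            "rho": float(rho), "spike_rate": float(spike_rate),
            "noise_sd": float(noise_sd), "amp_mean": float(amp_mean),
            "amp_sd": float(amp_sd), "spike_width": int(spike_width),
        },
    )
    return RamanScan(cube3, wavenumbers), gt


def gen_uv_image(
    shape=(128, 128),
    positive_fraction=0.2,
    contrast=10.0,
    background_level=100.0,
    signal_level=400.0,
    corr_length=6.0,
    seed=0,
):
    """Synthesize a bimodal UV-autofluorescence field.

    A smooth Gaussian random field is thresholded at the
    ``1 - positive_fraction`` quantile to form the positive mask, so the
    planted area fraction is exact up to pixel discreteness. Positive pixels
    take ``signal_level``, the rest ``background_level``; Gaussian noise of
    sd ``(signal_level - background_level) / contrast`` is added
    (``contrast=inf`` → noise-free).
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), corr_length)
    if positive_fraction == 0:
        mask = np.zeros(shape, dtype=bool)
    elif positive_fraction == 1:
        mask = np.ones(shape, dtype=bool)
    else:
        cut = np.quantile(field, 1.0 - positive_fraction)
        mask = field > cut
    img = np.where(mask, signal_level, background_level).astype(float)
    if np.isfinite(contrast):
        img = img + rng.normal(0.0, (signal_level - background_level) / contrast, size=shape)
    gt = GroundTruth(
        kind="uv_image",
        objects={"positive_mask": mask, "positive_fraction": float(mask.mean())},
        seed=int(seed),
        params={
            "shape": tuple(shape), "positive_fraction": float(positive_fraction),
            "contrast": float(contrast), "background_level": background_level,
            "signal_level": signal_level,
        },
    )
    return img, gt


def gen_if_field(
    shape=(128, 128),
    mask_fraction=0.3,
    asma_level_inside=100.0,
    asma_level_outside=10.0,
    pdgfrb_level_inside=200.0,
    pdgfrb_level_outside=20.0,
    noise_sd=2.0,
    corr_length=8.0,
    seed=0,
):
    """Synthesize a two-channel immunofluorescence field.

    Channel 0 is the PDGFR-β (mask-defining) stain, channel 1 the α-SMA
    stain; both are bimodal over the same smooth random mask covering
    ``mask_fraction`` of the field. Returns ``(image (2, H, W), GroundTruth)``.
    """
    if not 0.0 <= mask_fraction <= 1.0:
        raise ValueError("mask_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), corr_length)
    if mask_fraction == 0:
        mask = np.zeros(shape, dtype=bool)
    else:
        mask = field > np.quantile(field, 1.0 - mask_fraction)
    pdgfrb = np.where(mask, pdgfrb_level_inside, pdgfrb_level_outside).astype(float)
    asma = np.where(mask, asma_level_inside, asma_level_outside).astype(float)
    if noise_sd > 0:
        pdgfrb = pdgfrb + rng.normal(0.0, noise_sd, size=shape)
        asma = asma + rng.normal(0.0, noise_sd, size=shape)
    gt = GroundTruth(
        kind="if_field",
        objects={
            "mask": mask,
            "asma_mean_inside": float(asma_level_inside),
            "asma_mean_outside": float(asma_level_outside),
        },
        seed=int(seed),
        params={
            "shape": tuple(shape), "mask_fraction": float(mask_fraction),
            "asma_level_inside": asma_level_inside,
            "asma_level_outside": asma_level_outside, "noise_sd": noise_sd,
        },
    )
    return np.stack([pdgfrb, asma]), gt


def gen_assay_table(
    groups: dict,
    outliers: list | None = None,
    protein_conc=None,
    duration_h=48.0,
    seed=0,
):
    """Synthesize a long-format assay table with known group parameters.

    Parameters
    ----------
    groups : dict
        ``{condition: (mean, sd, n)}``; requires ``sd >= 0`` and ``n >= 2``.
    outliers : list of (condition, value)
        Values appended to the named group; their row indices are recorded
        in the ground truth.
    protein_conc : float | dict | None
        Per-sample protein concentration (mg/mL); a scalar applies to all
        rows, a dict maps condition → value. Defaults to 100 (the reference).

    Returns
    -------
    (pandas.DataFrame, GroundTruth)
        Columns: sample_id, condition, replicate, value, protein_conc,
        duration_h.
    """
    outliers = outliers or []
    rng = np.random.default_rng(seed)
    rows = []
    for cond, (mean, sd, n) in groups.items():
        if sd < 0:
            raise ValueError(f"group {cond!r}: sd must be non-negative")
        if n < 2:
            raise ValueError(f"group {cond!r}: need n >= 2 replicates")
        vals = np.full(n, float(mean)) if sd == 0 else rng.normal(mean, sd, size=n)
        for i, v in enumerate(vals):
            rows.append((cond, i, float(v)))
    outlier_indices = []
    for cond, value in outliers:
        if cond not in groups:
            raise ValueError(f"outlier group {cond!r} not in groups")
        outlier_indices.append(len(rows))
        rows.append((cond, sum(1 for r in rows if r[0] == cond), float(value)))

    df = pd.DataFrame(rows, columns=["condition", "replicate", "value"])
    df.insert(0, "sample_id", [f"{c}_{r}" for c, r in zip(df["condition"], df["replicate"])])
    if protein_conc is None:
        df["protein_conc"] = 100.0
    elif isinstance(protein_conc, dict):
        df["protein_conc"] = df["condition"].map(protein_conc).astype(float)
    else:
        df["protein_conc"] = float(protein_conc)
    df["duration_h"] = float(duration_h)

    gt = GroundTruth(
        kind="assay_table",
        objects={
            "groups": {k: tuple(v) for k, v in groups.items()},
            "outlier_indices": outlier_indices,
            "outlier_values": [v for _, v in outliers],
        },
        seed=int(seed),
        params={"groups": {k: tuple(v) for k, v in groups.items()},
                "outliers": list(outliers), "duration_h": float(duration_h)},
    )
    return df, gt
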