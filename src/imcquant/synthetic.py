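"""Synthetic multi-mouse IMC cohorts with per-pixel ground truth.

The simulator emulates the structure of cisplatin-treated pancreatic
xenograft sections: epithelial glands embedded in fibrous stroma,
collagen fibers that concentrate platinum, necrotic gland cores ringed by
hypoxia, scattered nuclei, and an instrument model with per-image
sensitivity drift, a spatially uniform xenon plasma background and a
small nearest-neighbour spot cross-contamination.

Emission is Poisson per pixel per channel: the expected count is

    lambda = baseline x marker-rule multiplier x drift_factor

where the marker rules place each stain on its target compartment
(Collagen I/aSMA on stroma, Pan-Keratin/E-cadherin on epithelium,
nuclear stains on nuclei, EF5 on the hypoxic rim, gH2AX on necrosis and
on drug-damaged epithelial nuclei, IdU/Ki-67 on S-phase nuclei).  The
platinum channel adds dose-dependent tissue signal on top of a small
instrument background, enriched on collagen pixels:

    lambda_Pt = baseline_Pt x drift x (1 + dose x signal_scale
                 x (1 + (enrichment - 1) x [collagen]) x [tissue])

so that untreated animals show only background-level platinum while the
collagen / epithelium intensity ratio in treated animals approaches the
configured enrichment.  The xenon channel is ``xe_mean_reference x drift``
everywhere, which is exactly the assumption that makes xenon-based
sensitivity normalization valid; tests may violate it deliberately.

Every stochastic operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import tifffile
import yaml
from scipy import ndimage as ndi

from .errors import ConfigError, PanelError, SimulationError
from .panel import Panel, default_panel
from .raw_io import (ChannelMeta, MultichannelImage, ScanGeometry,
                     write_sidecar)
from .region_quant import TissueClass

MIN_DIM = 64


@dataclass(frozen=True)
class GroupSpec:
    """A treatment arm: name plus a unitless dose scale (0 = untreated)."""

    name: str
    pt_dose_scale: float


def _default_baselines() -> dict[str, float]:
    # off-target / instrument background in counts per pixel
    return {
        "147Sm": 0.5, "158Gd": 0.5, "159Tb": 0.5, "162Dy": 0.5,
        "168Er": 0.5, "169Tm": 0.8, "175Lu": 0.8, "176Yb": 0.5,
        "191Ir": 1.0, "127I": 0.5, "195Pt": 0.2,
    }


@dataclass
class SimulationConfig:
    """Cohort geometry, tissue composition and instrument model.

    Densities are fractions of total image area.  ``drift_range`` bounds
    the per-image multiplicative sensitivity factor (drawn uniformly) and
    must contain 1.  ``crosstalk_rate`` is the fraction of each spot's
    signal deposited on its four neighbours, bounded by the instrument's
    stated <2% spot cross-contamination.
    """

    image_height: int = 256
    image_width: int = 256
    n_mice_per_group: int = 2
    n_images_per_mouse: int = 2
    groups: tuple[GroupSpec, ...] = (GroupSpec("control", 0.0),
                                     GroupSpec("cisplatin", 1.0))
    tissue_fraction: float = 0.90
    gland_density: float = 0.30
    fiber_density: float = 0.12
    necrosis_fraction: float = 0.04
    hypoxia_rim_width: int = 3
    nucleus_radius: int = 2
    nucleus_density: float = 0.12          # fraction of cellular area
    idu_positive_fraction: float = 0.30
    idu_dose_suppression: float = 4.0      # f_eff = f / (1 + k * dose)
    gh2ax_positive_fraction_treated: float = 0.40
    pt_collagen_enrichment: float = 5.0
    pt_signal_scale: float = 100.0
    marker_high_multiplier: float = 30.0
    channel_baselines: dict[str, float] = field(default_factory=_default_baselines)
    xe_mean_reference: float = 400.0
    drift_range: tuple[float, float] = (0.5, 2.0)
    crosstalk_rate: float = 0.015
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < MIN_DIM or self.image_width < MIN_DIM:
            raise ConfigError(f"image dimensions must be >= {MIN_DIM}x{MIN_DIM}")
        for name in ("tissue_fraction", "gland_density", "fiber_density",
                     "necrosis_fraction", "idu_positive_fraction",
                     "gh2ax_positive_fraction_treated", "nucleus_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.gland_density + self.fiber_density + self.necrosis_fraction > 1.0:
            raise ConfigError("gland + fiber + necrosis coverage exceeds the image")
        if self.gland_density + self.fiber_density + self.necrosis_fraction \
                > self.tissue_fraction + 1e-12:
            raise ConfigError("coverage targets exceed the tissue fraction")
        lo, hi = self.drift_range
        if not (0 < lo <= 1.0 <= hi):
            raise ConfigError(f"drift_range must satisfy 0 < lo <= 1 <= hi, got {self.drift_range}")
        if self.xe_mean_reference <= 0:
            raise ConfigError("xe_mean_reference must be positive")
        if not 0.0 <= self.crosstalk_rate <= 0.02:
            raise ConfigError("crosstalk_rate must lie in [0, 0.02]")
        if self.pt_collagen_enrichment < 1:
            raise ConfigError("pt_collagen_enrichment must be >= 1")
        if any(v < 0 for v in self.channel_baselines.values()):
            raise ConfigError("channel baselines must be non-negative")

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise ConfigError(f"unknown group {name!r}")


@dataclass
class GroundTruth:
    """Simulator truth for one image: label maps and expected intensities."""

    label_map: np.ndarray                   # (H, W) TissueClass values
    hypoxia_map: np.ndarray                 # (H, W) bool
    nucleus_map: np.ndarray                 # (H, W) bool
    nucleus_labels: np.ndarray              # (H, W) int, 0 = none
    lambda_maps: dict[str, np.ndarray] = field(default_factory=dict)
    drift_factor: Optional[float] = None
    group: str = ""
    mouse_id: str = ""
    image_id: str = ""
    idu_nuclei: Optional[np.ndarray] = None     # ids of IdU+ nuclei
    gh2ax_nuclei: Optional[np.ndarray] = None   # ids of gH2AX+ nuclei

    def class_mask(self, *classes: TissueClass) -> np.ndarray:
        return np.isin(self.label_map, [int(c) for c in classes])

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label_map != int(TissueClass.BACKGROUND)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def _smoothed_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    return ndi.gaussian_filter(rng.standard_normal(shape), sigma)


def _threshold_at_fraction(field_: np.ndarray, within: np.ndarray,
                           n_target: int) -> np.ndarray:
    """Boolean mask of the *n_target* highest-valued pixels of *field_* inside *within*."""
    vals = field_[within]
    if n_target <= 0:
        return np.zeros_like(within)
    if n_target >= vals.size:
        return within.copy()
    thr = np.partition(vals, vals.size - n_target)[vals.size - n_target]
    mask = within & (field_ >= thr)
    return mask


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy ** 2 + xx ** 2) <= r ** 2


def _random_walk_fiber(rng: np.random.Generator, shape, width_radius: int) -> np.ndarray:
    """Rasterized curvilinear fiber: a jittered-heading random walk, dilated."""
    h, w = shape
    length = int(rng.integers(max(h, w) // 2, 2 * max(h, w)))
    r, c = rng.uniform(0, h), rng.uniform(0, w)
    angle = rng.uniform(0, 2 * math.pi)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(length):
        angle += rng.normal(0.0, 0.2)
        r += math.sin(angle)
        c += math.cos(angle)
        ri, ci = int(r), int(c)
        if 0 <= ri < h and 0 <= ci < w:
            mask[ri, ci] = True
        else:
            break
    if mask.any():
        mask = ndi.binary_dilation(mask, structure=_disk(width_radius))
    return mask


def make_tissue_labels(config: SimulationConfig, seed: int) -> GroundTruth:
    """Generate label, hypoxia and nucleus maps for one image.

    Epithelial glands come from thresholded smoothed noise, collagen
    fibers from dilated random walks through the stroma, necrotic cores
    from eroded gland interiors, and the hypoxic rim from a dilation ring
    around necrosis.  Realized area fractions track the configured
    densities; fibers are added one walk at a time until the collagen
    target is met.
    """
    h, w = config.image_height, config.image_width
    n_px = h * w
    rng = np.random.default_rng(seed)

    # tissue footprint
    tissue_field = _smoothed_noise(rng, (h, w), sigma=max(h, w) / 6)
    tissue = _threshold_at_fraction(tissue_field, np.ones((h, w), bool),
                                    int(round(config.tissue_fraction * n_px)))

    # epithelial glands (includes future necrotic cores)
    gland_field = _smoothed_noise(rng, (h, w), sigma=max(h, w) / 16)
    n_gland = int(round(config.gland_density * n_px))
    if n_gland > int(tissue.sum()):
        raise SimulationError("gland target exceeds available tissue area")
    gland = _threshold_at_fraction(gland_field, tissue, n_gland)

    # necrotic cores inside a subset of glands
    necrosis = np.zeros((h, w), dtype=bool)
    n_necro_target = int(round(config.necrosis_fraction * n_px))
    if n_necro_target > 0:
        placed = 0
        for erode_r in (4, 3, 2):       # bounded retries with shallower erosion
            dist = ndi.distance_transform_edt(gland)
            cores, n_cores = ndi.label(dist > erode_r)
            order = rng.permutation(np.arange(1, n_cores + 1))
            for cid in order:
                if placed >= n_necro_target:
                    break
                core = cores == cid
                necrosis |= core
                placed = int(necrosis.sum())
            if placed >= n_necro_target:
                break
        if placed < 0.25 * n_necro_target:
            raise SimulationError(
                f"could not place necrosis fraction {config.necrosis_fraction} "
                f"inside glands after bounded retries")
    epithelium = gland & ~necrosis

    # hypoxic rim around necrosis
    hypoxia = np.zeros((h, w), dtype=bool)
    if necrosis.any() and config.hypoxia_rim_width > 0:
        dil = ndi.binary_dilation(necrosis, structure=_disk(config.hypoxia_rim_width))
        hypoxia = dil & ~necrosis & tissue

    # collagen fibers through the stroma
    stroma_area = tissue & ~gland
    collagen = np.zeros((h, w), dtype=bool)
    n_fiber_target = int(round(config.fiber_density * n_px))
    max_walks = 2000
    walks = 0
    while collagen.sum() < n_fiber_target and walks < max_walks:
        width_radius = int(rng.integers(1, 3))
        fib = _random_walk_fiber(rng, (h, w), width_radius) & stroma_area
        collagen |= fib
        walks += 1
    if collagen.sum() < 0.5 * n_fiber_target and n_fiber_target > 0:
        raise SimulationError("could not place requested fiber density after "
                              f"{max_walks} walks")

    labels = np.full((h, w), int(TissueClass.BACKGROUND), dtype=np.uint8)
    labels[tissue] = int(TissueClass.STROMA_OTHER)
    labels[collagen] = int(TissueClass.STROMA_COLLAGEN)
    labels[epithelium] = int(TissueClass.EPITHELIUM)
    labels[necrosis] = int(TissueClass.NECROSIS)

    # nuclei: disks scattered through cellular (non-necrotic) tissue with a
    # minimum separation so neighbouring nuclei stay resolvable
    cellular = np.isin(labels, [int(TissueClass.EPITHELIUM),
                                int(TissueClass.STROMA_COLLAGEN),
                                int(TissueClass.STROMA_OTHER)])
    rad = config.nucleus_radius
    disk_area = _disk(rad).sum()
    n_nuclei_target = int(config.nucleus_density * cellular.sum() / disk_area)
    nucleus_map = np.zeros((h, w), dtype=bool)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    blocked = np.zeros((h, w), dtype=bool)
    sep = 2 * rad + 3
    # centers only where the whole disk fits inside cellular tissue
    interior = ndi.binary_erosion(cellular, structure=_disk(rad))
    cand_r, cand_c = np.nonzero(interior)
    order = rng.permutation(cand_r.size)
    nid = 0
    for idx in order:
        if nid >= n_nuclei_target:
            break
        r, c = int(cand_r[idx]), int(cand_c[idx])
        if blocked[r, c]:
            continue
        if r - rad < 0 or r + rad >= h or c - rad < 0 or c + rad >= w:
            continue
        nid += 1
        rr, cc = np.nonzero(_disk(rad))
        nucleus_map[r + rr - rad, c + cc - rad] = True
        nucleus_labels[r + rr - rad, c + cc - rad] = nid
        r0, r1 = max(0, r - sep), min(h, r + sep + 1)
        c0, c1 = max(0, c - sep), min(w, c + sep + 1)
        blocked[r0:r1, c0:c1] = True

    return GroundTruth(labels, hypoxia, nucleus_map, nucleus_labels)


# ---------------------------------------------------------------------------
# channel simulation
# ---------------------------------------------------------------------------

_REQUIRED_SIM_MARKERS = ("Collagen I", "aSMA", "Pan-Keratin", "E-cadherin",
                         "Histone H3", "Ir-Intercalator", "IdU", "EF5",
                         "gH2AX", "Ki-67")


def _nucleus_ids_in(truth: GroundTruth, region_mask: np.ndarray,
                    exclude: Optional[np.ndarray] = None) -> np.ndarray:
    """Nucleus ids whose pixels lie (by majority) in *region_mask*."""
    lab = truth.nucleus_labels
    ids = np.unique(lab[lab > 0])
    if ids.size == 0:
        return ids
    inside = ndi.mean(region_mask.astype(float), lab, ids)
    keep = inside > 0.5
    if exclude is not None:
        excl = ndi.mean(exclude.astype(float), lab, ids) > 0.5
        keep &= ~excl
    return ids[keep]


def simulate_channels(truth: GroundTruth, config: SimulationConfig,
                      panel: Panel, seed: int,
                      drift_factor: Optional[float] = None) -> MultichannelImage:
    """Draw Poisson ion counts for every panel channel from the label maps.

    The per-image drift factor is drawn uniformly from ``drift_range``
    unless given explicitly; it multiplies the expected counts of every
    channel, including xenon.  Expected-count (lambda) maps are stored on
    the ground truth for oracle-style tests.
    """
    panel.require_markers(_REQUIRED_SIM_MARKERS)
    panel.require_roles(("drug", "background"))
    rng = np.random.default_rng(seed)
    drift = float(drift_factor) if drift_factor is not None \
        else float(rng.uniform(*config.drift_range))
    if not config.drift_range[0] <= drift <= config.drift_range[1]:
        raise ConfigError("drift_factor outside configured drift_range")

    group = config.group(truth.group) if truth.group else GroupSpec("", 0.0)
    dose = group.pt_dose_scale
    hi = config.marker_high_multiplier
    base = config.channel_baselines

    lab = truth.label_map
    epith = lab == int(TissueClass.EPITHELIUM)
    coll = lab == int(TissueClass.STROMA_COLLAGEN)
    stroma = coll | (lab == int(TissueClass.STROMA_OTHER))
    necro = lab == int(TissueClass.NECROSIS)
    tissue = truth.tissue_mask
    nuc = truth.nucleus_map

    # nucleus phenotype assignment
    nlab = truth.nucleus_labels
    epi_ids = _nucleus_ids_in(truth, epith)
    nonhyp_epi_ids = _nucleus_ids_in(truth, epith, exclude=truth.hypoxia_map)
    f_idu = config.idu_positive_fraction / (1.0 + config.idu_dose_suppression * dose)
    n_idu = int(round(f_idu * nonhyp_epi_ids.size))
    idu_ids = rng.choice(nonhyp_epi_ids, size=n_idu, replace=False) \
        if n_idu else np.empty(0, dtype=int)
    idu_mask = np.isin(nlab, idu_ids)
    if dose > 0:
        n_gh = int(round(config.gh2ax_positive_fraction_treated * epi_ids.size))
        gh_ids = rng.choice(epi_ids, size=n_gh, replace=False) \
            if n_gh else np.empty(0, dtype=int)
    else:
        gh_ids = np.empty(0, dtype=int)
    gh_mask = np.isin(nlab, gh_ids)

    def mult(high_mask: np.ndarray) -> np.ndarray:
        return np.where(high_mask, hi, 1.0)

    lam: dict[str, np.ndarray] = {}
    for entry in panel:
        ch = entry.channel_name
        if entry.role == "background":
            lam[ch] = np.full(lab.shape, config.xe_mean_reference * drift)
            continue
        if entry.role == "drug":
            b = base.get(ch, 0.2)
            enrich = 1.0 + (config.pt_collagen_enrichment - 1.0) * coll
            lam[ch] = b * drift * (1.0 + dose * config.pt_signal_scale
                                   * enrich * tissue)
            continue
        b = base.get(ch, 0.5)
        marker = entry.marker
        if marker == "Collagen I":
            m = mult(coll)
        elif marker == "aSMA":
            m = mult(stroma)
        elif marker in ("Pan-Keratin", "E-cadherin"):
            m = mult(epith)
        elif marker in ("Histone H3", "Ir-Intercalator"):
            m = mult(nuc)
        elif marker == "EF5":
            m = mult(truth.hypoxia_map)
        elif marker == "gH2AX":
            m = mult(necro | gh_mask)
        elif marker in ("IdU", "Ki-67"):
            m = mult(idu_mask)
        else:
            m = np.ones(lab.shape)
        lam[ch] = b * m * drift

    data = np.empty(lab.shape + (len(panel),), dtype=np.float64)
    for i, entry in enumerate(panel):
        data[:, :, i] = rng.poisson(lam[entry.channel_name]).astype(np.float64)

    truth.lambda_maps = lam
    truth.drift_factor = drift
    truth.idu_nuclei = idu_ids
    truth.gh2ax_nuclei = gh_ids
    meta = [ChannelMeta.from_name(e.channel_name, panel) for e in panel]
    prov = {"simulated": True, "group": truth.group, "mouse_id": truth.mouse_id,
            "image_id": truth.image_id, "drift_factor": drift}
    return MultichannelImage(data, meta, prov)


def apply_crosstalk(image: MultichannelImage, rate: float) -> MultichannelImage:
    """Spread *rate* of each spot's signal onto its four neighbours.

    Each pixel keeps ``1 - rate`` of its counts and sends ``rate / 4`` to
    each 4-neighbour; the share that would leave the image returns to its
    source so total counts per channel are conserved.  Returns a new
    image; the input is untouched.
    """
    if not 0.0 <= rate <= 0.05:
        raise ConfigError(f"crosstalk rate {rate} outside [0, 0.05]")
    if rate == 0.0:
        return image.copy()
    x = image.data
    r4 = rate / 4.0
    out = (1.0 - rate) * x.copy()
    out[1:, :, :] += r4 * x[:-1, :, :]
    out[:-1, :, :] += r4 * x[1:, :, :]
    out[:, 1:, :] += r4 * x[:, :-1, :]
    out[:, :-1, :] += r4 * x[:, 1:, :]
    # off-image shares return to their source row/column
    out[0, :, :] += r4 * x[0, :, :]
    out[-1, :, :] += r4 * x[-1, :, :]
    out[:, 0, :] += r4 * x[:, 0, :]
    out[:, -1, :] += r4 * x[:, -1, :]
    return MultichannelImage(out, list(image.channel_meta),
                             {**image.provenance, "crosstalk_rate": rate})


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_raw(image: MultichannelImage, path, sidecar_path=None,
               scan_pattern: str = "unidirectional", **sidecar_extra) -> Path:
    """Write the raw transient-signal text export plus its geometry sidecar.

    Rows are emitted in acquisition order for the requested raster
    pattern, with a leading push-index column and one column per mass
    channel.  Counts are written with full float precision so a read-back
    through :mod:`imcquant.raw_io` reproduces the image bit-exactly.
    Returns the sidecar path.
    """
    path = Path(path)
    geom = ScanGeometry(image.width, image.height, scan_pattern)
    from .raw_io import push_to_pixel
    k = np.arange(geom.n_pixels)
    rows, cols = push_to_pixel(k, geom)
    flat = image.data[rows, cols, :]
    with open(path, "w") as fh:
        fh.write("Push\t" + "\t".join(image.channel_names) + "\n")
        for i in range(flat.shape[0]):
            fh.write(str(i) + "\t" + "\t".join(repr(float(v)) for v in flat[i]) + "\n")
    if sidecar_path is None:
        sidecar_path = path.with_suffix(path.suffix + ".yaml")
    extra = {k_: image.provenance.get(k_) for k_ in ("mouse_id", "group", "image_id")}
    extra.update(sidecar_extra)
    write_sidecar(sidecar_path, geom, image.channel_names, **extra)
    return Path(sidecar_path)


def save_ground_truth(truth: GroundTruth, path, manifest_path=None) -> None:
    """Persist truth as a multipage TIFF (labels + lambda maps) and a manifest."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        tif.write(truth.label_map.astype(np.uint16), description="label_map",
                  contiguous=False)
        tif.write(truth.hypoxia_map.astype(np.uint16), description="hypoxia_map",
                  contiguous=False)
        tif.write(truth.nucleus_labels.astype(np.uint16), description="nucleus_labels",
                  contiguous=False)
        for name, lam in truth.lambda_maps.items():
            tif.write(lam.astype(np.float32), description=f"lambda:{name}",
                      contiguous=False)
    if manifest_path is None:
        manifest_path = path.with_suffix(".yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({
            "group": truth.group, "mouse_id": truth.mouse_id,
            "image_id": truth.image_id,
            "drift_factor": None if truth.drift_factor is None
            else float(truth.drift_factor),
            "idu_nuclei": [] if truth.idu_nuclei is None
            else [int(i) for i in truth.idu_nuclei],
            "gh2ax_nuclei": [] if truth.gh2ax_nuclei is None
            else [int(i) for i in truth.gh2ax_nuclei],
        }, fh, sort_keys=False)


def load_ground_truth(path, manifest_path=None) -> GroundTruth:
    path = Path(path)
    label_map = hypoxia = nuclab = None
    lam: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            desc = page.description or ""
            arr = page.asarray()
            if desc == "label_map":
                label_map = arr.astype(np.uint8)
            elif desc == "hypoxia_map":
                hypoxia = arr.astype(bool)
            elif desc == "nucleus_labels":
                nuclab = arr.astype(np.int32)
            elif desc.startswith("lambda:"):
                lam[desc.split(":", 1)[1]] = arr.astype(np.float64)
    if label_map is None or hypoxia is None or nuclab is None:
        raise SimulationError(f"{path}: incomplete ground-truth TIFF")
    truth = GroundTruth(label_map, hypoxia, nuclab > 0, nuclab, lam)
    if manifest_path is None:
        manifest_path = path.with_suffix(".yaml")
    if Path(manifest_path).exists():
        with open(manifest_path) as fh:
            doc = yaml.safe_load(fh)
        truth.group = doc.get("group", "")
        truth.mouse_id = doc.get("mouse_id", "")
        truth.image_id = doc.get("image_id", "")
        truth.drift_factor = doc.get("drift_factor")
        truth.idu_nuclei = np.asarray(doc.get("idu_nuclei", []), dtype=int)
        truth.gh2ax_nuclei = np.asarray(doc.get("gh2ax_nuclei", []), dtype=int)
    return truth


# ---------------------------------------------------------------------------
# cohort convenience
# ---------------------------------------------------------------------------

def simulate_image(config: SimulationConfig, group: str, mouse_id: str,
                   image_id: str, seed: int,
                   panel: Optional[Panel] = None,
                   drift_factor: Optional[float] = None,
                   crosstalk: Optional[float] = None,
                   ) -> tuple[MultichannelImage, GroundTruth]:
    """Tissue labels -> channels -> crosstalk for a single image."""
    panel = panel or default_panel()
    ss = np.random.SeedSequence(seed)
    s_label, s_chan = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    truth = make_tissue_labels(config, s_label)
    truth.group, truth.mouse_id, truth.image_id = group, mouse_id, image_id
    image = simulate_channels(truth, config, panel, s_chan, drift_factor=drift_factor)
    rate = config.crosstalk_rate if crosstalk is None else crosstalk
    if rate > 0:
        image = apply_crosstalk(image, rate)
    return image, truth


def simulate_cohort(config: SimulationConfig, seed: Optional[int] = None,
                    panel: Optional[Panel] = None,
                    ) -> list[tuple[MultichannelImage, GroundTruth]]:
    """All groups x mice x images, with deterministic per-image sub-seeds."""
    panel = panel or default_panel()
    root = np.random.SeedSequence(config.rng_seed if seed is None else seed)
    out = []
    n_images = (len(config.groups) * config.n_mice_per_group
                * config.n_images_per_mouse)
    subs = root.spawn(n_images)
    i = 0
    for g in config.groups:
        for m in range(config.n_mice_per_group):
            mouse_id = f"{g.name}_m{m + 1}"
            for k in range(config.n_images_per_mouse):
                image_id = f"{mouse_id}_img{k + 1}"
                s = int(subs[i].generate_state(1)[0] % (2 ** 31))
                i += 1
                out.append(simulate_image(config, g.name, mouse_id, image_id,
                                          s, panel=panel))
    return out
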