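"""Tissue-region classification, nucleus segmentation and quantification.

Regions are assigned from marker channels with a transparent score-based
rule set: stromal score from Collagen I and aSMA, epithelial score from
Pan-Keratin and E-cadherin, tissue/background split on total ion current,
necrosis from low nuclear signal combined with high gH2AX.  Every
threshold defaults to Otsu's method on the relevant smoothed channel and
can be overridden with absolute values for reproducibility.

Quantification emits one record per image x region x channel with mean,
SD and pixel count; "viable" summaries exclude necrosis, and the drug
(platinum) channel additionally gets paired collagen vs non-collagen
viable-tissue records, since collagen-bound drug is the quantity of
interest.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .errors import DataError, PanelError
from .panel import Panel, normalize_channel_name
from .raw_io import MultichannelImage, compute_tic


class TissueClass(enum.IntEnum):
    """Per-pixel tissue classes shared by the simulator and the classifier."""

    BACKGROUND = 0
    EPITHELIUM = 1
    STROMA_COLLAGEN = 2
    STROMA_OTHER = 3
    NECROSIS = 4
    UNCLASSIFIED = 5


#: Classes counted as tissue (anything but background/unclassified).
TISSUE_CLASSES = (TissueClass.EPITHELIUM, TissueClass.STROMA_COLLAGEN,
                  TissueClass.STROMA_OTHER, TissueClass.NECROSIS)
#: Classes counted as viable tissue (tissue minus necrosis).
VIABLE_CLASSES = (TissueClass.EPITHELIUM, TissueClass.STROMA_COLLAGEN,
                  TissueClass.STROMA_OTHER)

CLASS_NAMES = {c: c.name.lower() for c in TissueClass}


@dataclass
class RegionMask:
    labels: np.ndarray                       # (H, W) uint8 of TissueClass values
    class_scores: dict = field(default_factory=dict)   # name -> (H, W) float
    provenance: dict = field(default_factory=dict)     # thresholds used

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        valid = {int(c) for c in TissueClass}
        if not set(np.unique(self.labels)).issubset(valid):
            raise DataError("region mask contains labels outside the class set")

    def mask(self, *classes: TissueClass) -> np.ndarray:
        return np.isin(self.labels, [int(c) for c in classes])

    def n_pixels(self, *classes: TissueClass) -> int:
        return int(self.mask(*classes).sum())


@dataclass
class QuantRecord:
    """Per-image, per-region, per-channel intensity summary."""

    image_id: str
    mouse_id: str
    group: str
    region: str
    channel: str
    mean: float
    sd: float
    n_pixels: int
    normalized: bool = False
    pct_positive: Optional[float] = None
    mean_se: Optional[float] = None          # standard error of the mean

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise DataError("QuantRecord requires n_pixels > 0")
        if self.sd < 0:
            raise DataError("QuantRecord requires sd >= 0")
        if self.pct_positive is not None and not (0 <= self.pct_positive <= 100):
            raise DataError("pct_positive must lie in [0, 100]")
        if self.mean_se is None:
            self.mean_se = self.sd / math.sqrt(self.n_pixels)


def records_to_frame(records: Iterable[QuantRecord]) -> pd.DataFrame:
    rows = [vars(r).copy() for r in records]
    return pd.DataFrame(rows)


@dataclass
class NucleusSet:
    """Connected-component nuclei with per-nucleus summaries.

    ``table`` columns: nucleus_id, row, col, area, region and one
    ``mean_<channel>`` column per image channel.
    """

    labels: np.ndarray          # (H, W) int label image, 0 = background
    table: pd.DataFrame

    @property
    def n_nuclei(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierParams:
    """Tunables of the marker-score region classifier.

    All thresholds default to ``None`` meaning Otsu on the relevant
    smoothed channel; set absolute count values to pin them down.
    ``class_threshold`` is on the rescaled [0, 1] score scale.
    """

    smooth_sigma: float = 1.0
    clip_percentile: float = 99.0
    class_threshold: float = 0.1
    tissue_threshold: Optional[float] = None      # on smoothed TIC
    collagen_threshold: Optional[float] = None    # on smoothed Collagen I
    nuclear_threshold: Optional[float] = None     # on smoothed nuclear mean
    gh2ax_threshold: Optional[float] = None       # on smoothed gH2AX
    necrosis_rule: bool = True


def _smooth(chan: np.ndarray, sigma: float) -> np.ndarray:
    arr = np.where(np.isfinite(chan), chan, 0.0)
    if sigma <= 0:
        return arr
    return ndi.gaussian_filter(arr, sigma)


def _rescale(chan: np.ndarray, clip_percentile: float) -> np.ndarray:
    """Percentile-clip then min-max scale to [0, 1] (unit-free score input)."""
    finite = chan[np.isfinite(chan)]
    if finite.size == 0:
        return np.zeros_like(chan)
    hi = np.percentile(finite, clip_percentile)
    lo = float(finite.min())
    if hi <= lo:
        return np.zeros_like(chan)
    return np.clip((chan - lo) / (hi - lo), 0.0, 1.0)


def _otsu(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0 or values.min() == values.max():
        return float("inf")
    return float(threshold_otsu(values))


def classify_regions(image: MultichannelImage, panel: Panel,
                     params: Optional[ClassifierParams] = None) -> RegionMask:
    """Assign each pixel a tissue class from marker-channel scores.

    Requires stromal (Collagen I, aSMA), epithelial (Pan-Keratin,
    E-cadherin) and nuclear channels in the panel.
    """
    params = params or ClassifierParams()
    panel.require_markers(("Collagen I", "aSMA", "Pan-Keratin", "E-cadherin"))
    panel.require_roles(("nuclear",))
    sig = params.smooth_sigma

    coll = _smooth(image.channel(panel.channel_for_marker("Collagen I")), sig)
    asma = _smooth(image.channel(panel.channel_for_marker("aSMA")), sig)
    pank = _smooth(image.channel(panel.channel_for_marker("Pan-Keratin")), sig)
    ecad = _smooth(image.channel(panel.channel_for_marker("E-cadherin")), sig)

    stromal_score = 0.5 * (_rescale(coll, params.clip_percentile)
                           + _rescale(asma, params.clip_percentile))
    epithelial_score = 0.5 * (_rescale(pank, params.clip_percentile)
                              + _rescale(ecad, params.clip_percentile))

    tic = compute_tic(image)
    acquired = np.isfinite(tic)
    tic_s = _smooth(tic, sig)
    if params.tissue_threshold is not None:
        tissue_thr = params.tissue_threshold
    else:
        # Otsu in log space: the TIC distribution is heavy-tailed (a
        # drug-rich compartment can dwarf the rest), which breaks the
        # bimodality assumption on the raw counts scale
        tissue_thr = float(np.expm1(_otsu(np.log1p(tic_s[acquired]))))
        if not np.isfinite(tissue_thr):
            # constant TIC: all-tissue if positive, all-background if zero
            tissue_thr = 0.0
    tissue = acquired & (tic_s > tissue_thr)

    labels = np.full(tic.shape, int(TissueClass.BACKGROUND), dtype=np.uint8)
    labels[~acquired] = int(TissueClass.BACKGROUND)

    score = np.stack([epithelial_score, stromal_score], axis=0)
    winner = np.argmax(score, axis=0)           # 0 = epithelium, 1 = stroma
    winning = np.max(score, axis=0)
    confident = tissue & (winning >= params.class_threshold)
    labels[tissue] = int(TissueClass.UNCLASSIFIED)
    labels[confident & (winner == 0)] = int(TissueClass.EPITHELIUM)
    labels[confident & (winner == 1)] = int(TissueClass.STROMA_OTHER)

    # collagen-positive sub-label within stroma
    stroma = labels == int(TissueClass.STROMA_OTHER)
    coll_thr = (params.collagen_threshold if params.collagen_threshold is not None
                else _otsu(coll[tissue]))
    labels[stroma & (coll > coll_thr)] = int(TissueClass.STROMA_COLLAGEN)

    thresholds = {"tissue": float(tissue_thr), "collagen": float(coll_thr),
                  "class_score": params.class_threshold}

    if params.necrosis_rule:
        nuc_channels = [image.channel(c) for c in image.channels_by_role("nuclear")]
        if not nuc_channels:
            nuc_channels = [image.channel(panel.by_role("nuclear")[0].channel_name)]
        nuclear = _smooth(np.mean([np.where(np.isfinite(c), c, 0.0) for c in nuc_channels],
                                  axis=0), sig)
        gh2ax = _smooth(image.channel(panel.channel_for_marker("gH2AX")), sig)
        nuc_thr = (params.nuclear_threshold if params.nuclear_threshold is not None
                   else _otsu(nuclear[tissue]))
        gh_thr = (params.gh2ax_threshold if params.gh2ax_threshold is not None
                  else _otsu(gh2ax[tissue]))
        necro = tissue & (nuclear < nuc_thr) & (gh2ax > gh_thr)
        # necrosis must out-score the lineage markers as well: keep pixels
        # that did not get a confident epithelial/stromal call, plus
        # low-score tissue, so gH2AX halos around damaged nuclei inside
        # intact epithelium are not relabelled.
        necro &= winning < max(params.class_threshold, 0.25)
        labels[necro] = int(TissueClass.NECROSIS)
        thresholds.update({"nuclear": float(nuc_thr), "gh2ax": float(gh_thr)})

    scores = {"epithelial": epithelial_score, "stromal": stromal_score}
    return RegionMask(labels, scores, {"thresholds": thresholds,
                                       "params": vars(params).copy()})


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

@dataclass
class NucleusParams:
    smooth_sigma: float = 1.0
    threshold: Optional[float] = None      # None -> Otsu
    min_nucleus_area: int = 4
    watershed_split: bool = False
    min_distance: int = 3


def segment_nuclei(image: MultichannelImage, panel: Panel,
                   params: Optional[NucleusParams] = None,
                   mask: Optional[RegionMask] = None) -> NucleusSet:
    """Threshold-and-label nucleus segmentation on the mean nuclear channel.

    Otsu threshold on the Gaussian-smoothed mean of the nuclear channels
    (Ir intercalator, Histone H3), connected components, small-object
    removal, and optional watershed splitting of touching nuclei.  If a
    region mask is supplied each nucleus is tagged with the tissue class
    at its centroid.
    """
    params = params or NucleusParams()
    panel.require_roles(("nuclear",))
    nuc_names = [e.channel_name for e in panel.by_role("nuclear")
                 if e.channel_name in image.channel_names]
    if not nuc_names:
        raise PanelError("no nuclear channel present in image")
    stack = [np.where(np.isfinite(image.channel(c)), image.channel(c), 0.0)
             for c in nuc_names]
    nuclear = _smooth(np.mean(stack, axis=0), params.smooth_sigma)

    thr = params.threshold if params.threshold is not None else _otsu(nuclear)
    fg = nuclear > thr
    if fg.any():
        fg = remove_small_objects(fg, max_size=params.min_nucleus_area - 1)
    if params.watershed_split and fg.any():
        dist = ndi.distance_transform_edt(fg)
        peaks = peak_local_max(dist, min_distance=params.min_distance, labels=fg)
        markers = np.zeros_like(dist, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers, mask=fg)
    else:
        labels, _ = ndi.label(fg)
    labels = np.asarray(labels, dtype=np.int32)

    ids = np.arange(1, labels.max() + 1)
    rows: dict[str, list] = {"nucleus_id": [], "row": [], "col": [], "area": [],
                             "region": []}
    chan_means: dict[str, np.ndarray] = {}
    if len(ids):
        areas = ndi.sum_labels(np.ones_like(labels), labels, ids)
        keep = areas >= params.min_nucleus_area
        ids = ids[keep]
    if len(ids):
        coms = ndi.center_of_mass(np.ones_like(labels), labels, ids)
        areas = ndi.sum_labels(np.ones_like(labels), labels, ids)
        for name in image.channel_names:
            chan = np.where(np.isfinite(image.channel(name)), image.channel(name), 0.0)
            chan_means[f"mean_{name}"] = ndi.mean(chan, labels, ids)
        for i, nid in enumerate(ids):
            r, c = int(round(coms[i][0])), int(round(coms[i][1]))
            rows["nucleus_id"].append(int(nid))
            rows["row"].append(r)
            rows["col"].append(c)
            rows["area"].append(int(areas[i]))
            if mask is not None:
                rows["region"].append(CLASS_NAMES[TissueClass(mask.labels[r, c])])
            else:
                rows["region"].append(None)
    table = pd.DataFrame(rows)
    for name, vals in chan_means.items():
        table[name] = vals
    # relabel to keep only surviving nuclei
    if labels.max() and len(ids) < labels.max():
        lut = np.zeros(labels.max() + 1, dtype=np.int32)
        lut[ids] = ids
        labels = lut[labels]
    return NucleusSet(labels, table)


def positive_fraction(nuclei: NucleusSet, channel: str,
                      threshold: Union[float, str] = "otsu",
                      region: Optional[str] = None,
                      exclude_channel: Optional[str] = None) -> float:
    """Percent of nuclei whose mean channel intensity exceeds a threshold.

    ``threshold`` may be an absolute count value or ``"otsu"`` (default),
    which splits the per-nucleus mean distribution.  ``region`` restricts
    the computation to nuclei tagged with that tissue class.
    ``exclude_channel`` drops nuclei whose mean on another channel
    exceeds four times the cohort median (a background-relative rule that
    stays put when no positive population exists) — e.g. gating out
    EF5-positive (hypoxic) nuclei when estimating an S-phase fraction,
    since hypoxic cells do not cycle.
    """
    if nuclei.n_nuclei == 0:
        raise DataError("empty nucleus set")
    table = nuclei.table
    if region is not None:
        table = table[table["region"] == region]
        if table.empty:
            raise DataError(f"no nuclei in region {region!r}")
    if exclude_channel is not None:
        xcol = f"mean_{normalize_channel_name(exclude_channel)}"
        if xcol not in table.columns:
            raise DataError(f"channel {exclude_channel!r} has no per-nucleus means")
        xvals = table[xcol].to_numpy(dtype=float)
        table = table[xvals <= 4.0 * max(np.median(xvals), 1e-12)]
        if table.empty:
            raise DataError("all nuclei excluded by the gating channel")
    col = f"mean_{normalize_channel_name(channel)}"
    if col not in table.columns:
        raise DataError(f"channel {channel!r} has no per-nucleus means")
    vals = table[col].to_numpy(dtype=float)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise DataError(f"unknown threshold rule {threshold!r}")
        if np.min(vals) == np.max(vals):
            warnings.warn("constant per-nucleus intensities; no positive class")
            return 0.0
        thr = float(threshold_otsu(vals))
    else:
        thr = float(threshold)
    return 100.0 * float(np.mean(vals > thr))


# ---------------------------------------------------------------------------
# region means
# ---------------------------------------------------------------------------

def _region_stats(chan: np.ndarray, sel: np.ndarray) -> tuple[float, float, int]:
    vals = chan[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), float("nan"), 0
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0, int(vals.size)


def region_channel_means(image: MultichannelImage, mask: RegionMask,
                         channels: Optional[Sequence[str]] = None,
                         *, image_id: str = "", mouse_id: str = "",
                         group: str = "") -> list[QuantRecord]:
    """Mean, SD and pixel count per (region, channel).

    Emits one record per tissue class present, plus — for channels with
    the ``drug`` role — paired ``viable_collagen`` / ``viable_noncollagen``
    records over viable tissue (necrosis excluded), the comparison the
    collagen-binding question needs.  Empty regions are omitted with a
    warning rather than reported as zero.
    """
    if mask.labels.shape != image.data.shape[:2]:
        raise DataError("mask and image shapes differ")
    names = ([normalize_channel_name(c) for c in channels]
             if channels is not None else image.channel_names)
    records: list[QuantRecord] = []
    region_sels = [(CLASS_NAMES[c], mask.mask(c)) for c in TISSUE_CLASSES]
    drug_roles = {m.name for m in image.channel_meta if m.role == "drug"}
    coll = mask.mask(TissueClass.STROMA_COLLAGEN)
    viable = mask.mask(*VIABLE_CLASSES)
    extra_sels = [("viable_collagen", viable & coll),
                  ("viable_noncollagen", viable & ~coll)]
    for name in names:
        chan = image.channel(name)
        sels = region_sels + (extra_sels if name in drug_roles else [])
        for region_name, sel in sels:
            mean, sd, n = _region_stats(chan, sel)
            if n == 0:
                warnings.warn(f"region {region_name!r} empty in image {image_id!r}; "
                              f"record omitted")
                continue
            records.append(QuantRecord(image_id, mouse_id, group, region_name,
                                       name, mean, sd, n))
    return records
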