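"""Wound segmentation inside the previously computed skin mask.

The wound margin has the best contrast in the visual image's green channel,
so candidate margins are Canny edges of G, cleaned by a morphological opening
and labelled. Edges caused by structures inside the wound (necrosis, crusts,
fluids) are discarded by a temperature filter: the wound temperature at the
margin is lower than inside the wound, so only edges whose mean temperature
does not exceed the average of all per-edge means are kept. Each surviving
edge then seeds a region growing whose condition is an equal-or-darker
grayscale value relative to the seed, confined to the skin mask. The final
step is a user review: selecting one or more candidate labels, or overriding
the result with a manually drawn mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._growth import grow, structuring_element
from .errors import NoCandidateError, UsageError
from .imaging import BinaryMask, ImagePair, ThermalImage, VisualImage
from .skin import SkinSegmentationConfig, detect_edges


@dataclass
class WoundCandidates:
    """Labelled wound-candidate regions plus a per-candidate summary table."""

    labels: np.ndarray  # 0 = background, 1..K = candidates
    table: pd.DataFrame  # columns: label, area_px, mean_temp_C

    @property
    def n(self) -> int:
        return int(self.labels.max())

    def mask_for(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class SelectionInput:
    """User review outcome: pick candidate labels, or supply a manual mask."""

    mode: str  # "select" | "manual"
    selected_ids: list[int] | None = None
    manual_mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        if self.mode == "select":
            if not self.selected_ids:
                raise UsageError("select mode requires at least one candidate id")
        elif self.mode == "manual":
            if self.manual_mask is None or self.manual_mask.area == 0:
                raise UsageError("manual mode requires a non-empty mask")
        else:
            raise UsageError(f"unknown selection mode: {self.mode!r}")


def green_edges(
    visual: VisualImage,
    config: SkinSegmentationConfig | None = None,
    within: BinaryMask | None = None,
) -> np.ndarray:
    """Labelled Canny edges of the green channel.

    The edge mask is cleaned of speckles before labelling: edge components
    smaller than ``morph_kernel**2`` pixels are dropped. Canny curves are one
    pixel wide, so a plain area opening (rather than a structural one, which
    would erase thin curves wholesale) is the cleanup that deletes speckled
    pixels while preserving extended borders. When ``within`` is given (the
    visual skin mask), only edges inside its interior are kept, so the
    skin/background silhouette itself is never proposed as a wound.
    """
    config = config or SkinSegmentationConfig()
    edges = detect_edges(visual.g, config).as_bool()
    if within is not None:
        interior = ndimage.binary_erosion(
            within.as_bool(), structure=np.ones((3, 3), dtype=bool), iterations=5
        )
        edges &= interior
    structure = structuring_element(config.connectivity)
    comp, n_comp = ndimage.label(edges, structure=structure)
    if n_comp:
        areas = np.bincount(comp.ravel())
        areas[0] = 0
        small = np.flatnonzero(areas < config.morph_kernel**2)
        edges &= ~np.isin(comp, small)
    labels, n = ndimage.label(edges, structure=structuring_element(config.connectivity))
    if n == 0:
        raise NoCandidateError("no edges found in the green channel")
    return labels


def filter_edges_by_temperature(
    labelled_edges: np.ndarray, thermal: ThermalImage
) -> np.ndarray:
    """Keep only edges at least as cold as the average of per-edge means.

    Each edge's mean temperature along its pixels is computed; the unweighted
    average of those means is the reference; edges with a strictly greater
    mean are discarded (so a single edge, or ties at the average, survive).
    """
    n = int(labelled_edges.max())
    if n == 0:
        raise NoCandidateError("no labelled edges to filter")
    ids = np.arange(1, n + 1)
    means = ndimage.mean(thermal.temperatures, labels=labelled_edges, index=ids)
    reference = float(np.mean(means))
    keep = ids[means <= reference]
    if keep.size == 0:
        raise NoCandidateError("all edges discarded by the temperature filter")
    out = np.where(np.isin(labelled_edges, keep), labelled_edges, 0)
    return out


def grow_wound_regions(
    labelled_edges: np.ndarray,
    visual: VisualImage,
    skin_mask: BinaryMask,
    thermal: ThermalImage,
    config: SkinSegmentationConfig | None = None,
) -> WoundCandidates:
    """Region-grow each surviving edge into a wound candidate.

    For each edge independently, the admission condition is a grayscale luma
    less than or equal to the mean luma of that edge's pixels (the wound area
    appears darker than normal skin), restricted to the skin mask. Per-edge
    results are merged with lowest-label priority and relabelled 1..K in
    row-major order of each candidate's first pixel, which makes the result
    independent of seed processing order.
    """
    config = config or SkinSegmentationConfig()
    ids = np.unique(labelled_edges)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise NoCandidateError("no surviving edges to grow from")
    luma = visual.luma()
    skin = skin_mask.as_bool()
    merged = np.zeros(labelled_edges.shape, dtype=int)
    for edge_id in ids:
        seed = labelled_edges == edge_id
        threshold = float(luma[seed].mean())
        allowed = (luma <= threshold) & skin
        region = grow(seed, allowed, connectivity=config.connectivity)
        merged = np.where((merged == 0) & region, int(edge_id), merged)
    if not np.any(merged):
        raise NoCandidateError("region growing produced no wound candidates")
    # relabel consecutively, ordered by first pixel in row-major order
    old_ids = np.unique(merged)
    old_ids = old_ids[old_ids > 0]
    order = sorted(old_ids, key=lambda i: int(np.flatnonzero(merged.ravel() == i)[0]))
    labels = np.zeros_like(merged)
    rows = []
    for new_id, old_id in enumerate(order, start=1):
        member = merged == old_id
        labels[member] = new_id
        rows.append(
            {
                "label": new_id,
                "area_px": int(member.sum()),
                "mean_temp_C": float(thermal.temperatures[member].mean()),
            }
        )
    return WoundCandidates(labels=labels, table=pd.DataFrame(rows))


def apply_selection(candidates: WoundCandidates, selection: SelectionInput) -> BinaryMask:
    """Resolve the user review into the final wound mask."""
    if selection.mode == "manual":
        mask = selection.manual_mask
        if mask.shape != candidates.labels.shape:
            raise UsageError(
                f"manual mask shape {mask.shape} does not match image {candidates.labels.shape}"
            )
        return BinaryMask(mask.values.copy(), role="wound")
    missing = [i for i in selection.selected_ids if i < 1 or i > candidates.n]
    if missing:
        raise UsageError(
            f"selected candidate ids {missing} do not exist (have 1..{candidates.n})"
        )
    chosen = np.isin(candidates.labels, selection.selected_ids)
    return BinaryMask(chosen.astype(np.uint8), role="wound")


def segment_wound(
    pair: ImagePair,
    visual_skin_mask: BinaryMask,
    selection: SelectionInput | None,
    config: SkinSegmentationConfig | None = None,
) -> tuple[BinaryMask, WoundCandidates]:
    """Full wound segmentation: edges -> temperature filter -> growth -> review.

    Returns the final wound mask (the wound base used for scoring) together
    with the candidate set. If ``selection`` is None the candidate table is
    attached to the raised error so a non-interactive caller can inspect it
    and re-run with an explicit selection.
    """
    if visual_skin_mask.area == 0:
        raise UsageError("wound segmentation requires a non-empty skin mask")
    config = config or SkinSegmentationConfig()
    labelled = green_edges(pair.visual, config, within=visual_skin_mask)
    labelled = filter_edges_by_temperature(labelled, pair.thermal)
    candidates = grow_wound_regions(labelled, pair.visual, visual_skin_mask, pair.thermal, config)
    if selection is None:
        err = NoCandidateError(
            "no selection provided; candidate table available on this error"
        )
        err.candidates = candidates
        raise err
    wound = apply_selection(candidates, selection)
    return wound, candidates
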