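"""Static renderings of the four alignment views.

* pixel view: one colored rectangle per residue (PIL raster);
* logo view: conservation bars plus a frequency-scaled letter stack;
* identity heatmap: the all-vs-all percent-identity matrix as a raster;
* sequence space: embedding scatter, optionally colored by an annotation;
* coupling overlay: top-ranked coupling arcs above the displayed columns.

Rasters (pixel view, heatmap) are pure functions of their inputs: identical
alignment, scheme and cell size produce byte-identical images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")  # noqa: E402 — headless by design
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D
from PIL import Image

from . import alphabet, palettes
from .column_stats import MAX_BITS, ColumnProfile, ReferenceMask
from .errors import CouplingPositionError
from .msa_io import Alignment, AnnotationTable, CouplingSet
from .seq_metrics import PairwiseMatrix
from .seqspace import Embedding

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColorScheme:
    """A named residue palette; ``reference_dependent`` schemes compare to the reference row."""

    name: str
    palette: dict[str, palettes.RGB]
    reference_dependent: bool = False

    def __post_init__(self) -> None:
        missing = set(alphabet.ALPHABET) - set(self.palette)
        if missing:
            raise ValueError(f"palette missing characters: {sorted(missing)}")

    def lut(self) -> np.ndarray:
        """(22, 3) uint8 lookup table in residue-code order."""
        return np.array([self.palette[c] for c in alphabet.ALPHABET], dtype=np.uint8)


SCHEMES = ("aa_properties", "hydrophobicity", "mutation_vs_reference")


def get_scheme(name: str) -> ColorScheme:
    if name == "aa_properties":
        return ColorScheme(name, palettes.aa_properties_palette())
    if name == "hydrophobicity":
        return ColorScheme(name, palettes.hydrophobicity_palette())
    if name == "mutation_vs_reference":
        return ColorScheme(name, palettes.aa_properties_palette(),
                           reference_dependent=True)
    raise ValueError(f"unknown color scheme {name!r}; choose from {SCHEMES}")


def render_pixel_view(aln: Alignment, scheme: ColorScheme | str = "aa_properties",
                      cell_px: int = 1,
                      mask: ReferenceMask | list[int] | None = None) -> Image.Image:
    """Whole-alignment raster with one ``cell_px`` x ``cell_px`` block per residue.

    Under ``mutation_vs_reference`` cells that match the reference residue
    are drawn desaturated and mismatches at full saturation; the reference
    row itself stays fully saturated.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if cell_px < 1:
        raise ValueError("cell_px must be >= 1")
    codes = aln.codes()
    if mask is not None:
        cols = mask.columns if isinstance(mask, ReferenceMask) else list(mask)
        codes = codes[:, cols]
    rgb = scheme.lut()[codes]                          # (N, L, 3)
    if scheme.reference_dependent:
        ref = codes[aln.reference_index]
        match = codes == ref[None, :]
        match[aln.reference_index] = False             # reference stays saturated
        faded = (255 - 0.25 * (255 - rgb.astype(np.float64))).round().astype(np.uint8)
        rgb = np.where(match[:, :, None], faded, rgb)
    if cell_px > 1:
        rgb = np.repeat(np.repeat(rgb, cell_px, axis=0), cell_px, axis=1)
    return Image.fromarray(rgb, mode="RGB")


# ---------------------------------------------------------------------------
# logo

_LOGO_FONT = FontProperties(family="DejaVu Sans", weight="bold")


def _letter_patch(ax, letter: str, x: float, y: float, height: float,
                  color) -> None:
    """A glyph stretched to fill [x, x+1] x [y, y+height] in data units."""
    path = TextPath((0, 0), letter, size=1.0, prop=_LOGO_FONT)
    bbox = path.get_extents()
    stretch = (Affine2D()
               .translate(-bbox.x0, -bbox.y0)
               .scale(1.0 / bbox.width, 1.0 / bbox.height)
               .scale(0.9, height)
               .translate(x + 0.05, y))
    ax.add_patch(PathPatch(stretch.transform_path(path), facecolor=color,
                           edgecolor="none"))


def render_logo(profiles: list[ColumnProfile],
                couplings: CouplingSet | None = None,
                top_k: int = 10,
                mask: ReferenceMask | None = None,
                scheme: ColorScheme | str = "aa_properties",
                ref_length: int | None = None):
    """Sequence logo with a conservation-bar track above.

    Per column the residue letters are stacked by ascending height (most
    frequent on top); the stack totals the column's information content in
    bits, and the bar above repeats that value.  When a coupling set is
    given, the ``top_k`` highest-scoring pairs are drawn as arcs above the
    bars (requires the reference mask to place positions).
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    n = len(profiles)
    n_rows = 3 if couplings is not None else 2
    heights = ([0.8, 1, 2] if couplings is not None else [1, 2])
    fig, axes = plt.subplots(n_rows, 1, sharex=True,
                             figsize=(max(4.0, min(0.28 * n, 40.0)), 3.2 + 0.8 * (n_rows - 2)),
                             gridspec_kw={"height_ratios": heights})
    ax_logo = axes[-1]
    ax_bar = axes[-2]

    info = [p.info_bits for p in profiles]
    ax_bar.bar(np.arange(n) + 0.5, info, width=0.85, color="#606060")
    ax_bar.set_ylabel("bits")
    ax_bar.set_ylim(0, MAX_BITS)

    for k, prof in enumerate(profiles):
        y = 0.0
        for res, h in sorted(prof.logo_heights.items(), key=lambda kv: (kv[1], kv[0])):
            if h <= 0:
                continue
            _letter_patch(ax_logo, res, k, y, h,
                          np.array(scheme.palette[res]) / 255.0)
            y += h
    ax_logo.set_xlim(0, n)
    ax_logo.set_ylim(0, MAX_BITS)
    ax_logo.set_ylabel("bits")
    ax_logo.set_xlabel("reference position" if mask is not None else "column")
    if mask is not None:
        ticks = np.linspace(0, n - 1, num=min(n, 10), dtype=int)
        ax_logo.set_xticks(ticks + 0.5)
        ax_logo.set_xticklabels([mask.ref_positions[t] for t in ticks])

    if couplings is not None:
        if mask is None:
            raise ValueError("coupling overlay requires the reference mask")
        render_coupling_overlay(mask, couplings, top_k, ax=axes[0],
                                ref_length=ref_length)
    fig.tight_layout()
    return fig


def render_coupling_overlay(mask_map: ReferenceMask, couplings: CouplingSet,
                            top_k: int, ax=None, ref_length: int | None = None):
    """Arcs for the ``top_k`` highest-scoring couplings over displayed columns.

    Pairs whose reference positions are not displayed (masked out) are
    skipped with a logged warning; positions beyond the ungapped reference
    length (``ref_length``, defaulting to the largest displayed position)
    raise :class:`CouplingPositionError`.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if ref_length is None:
        ref_length = max(mask_map.ref_positions)
    couplings.validate_positions(ref_length)
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 1.5))
    else:
        fig = ax.figure
    top = couplings.top(top_k)
    scores = [s for _, _, s in top] or [1.0]
    smin, smax = min(scores), max(scores)
    for i, j, score in top:
        oi = mask_map.ordinal_of_ref_position(i)
        oj = mask_map.ordinal_of_ref_position(j)
        if oi is None or oj is None:
            logger.warning("coupling (%d, %d) falls in masked-out columns; skipped",
                           i, j)
            continue
        x0, x1 = oi + 0.5, oj + 0.5
        xm, r = (x0 + x1) / 2.0, abs(x1 - x0) / 2.0
        theta = np.linspace(0.0, np.pi, 64)
        weight = 0.5 if smax == smin else 0.5 + 0.5 * (score - smin) / (smax - smin)
        ax.plot(xm + r * np.cos(theta), r * np.sin(theta) / max(r, 1e-9),
                color=(0.7 * (1 - weight), 0.1, 0.3 + 0.7 * weight),
                lw=0.8 + 1.8 * weight)
    ax.set_ylim(0, 1.1)
    ax.set_yticks([])
    for side in ("top", "left", "right"):
        ax.spines[side].set_visible(False)
    return fig


# ---------------------------------------------------------------------------
# heatmap

def render_identity_heatmap(m: PairwiseMatrix,
                            order: list[int] | None = None,
                            cell_px: int = 1,
                            cmap: str = "Blues") -> Image.Image:
    """N x N raster of the identity matrix, light (0%) to dark (100%).

    ``order`` optionally reorders rows and columns by a user-supplied
    permutation (for example a tree-derived sequence order produced
    externally); it must be a bijection over the matrix indices.
    """
    values = np.asarray(m.values, dtype=np.float64)
    if order is not None:
        order = list(order)
        if sorted(order) != list(range(values.shape[0])):
            raise ValueError("order must be a permutation of the matrix indices")
        values = values[np.ix_(order, order)]
    scale = 100.0 if m.kind == "identity_percent" else max(values.max(), 1.0)
    rgba = matplotlib.colormaps[cmap](values / scale)
    rgb = (rgba[:, :, :3] * 255).round().astype(np.uint8)
    if cell_px > 1:
        rgb = np.repeat(np.repeat(rgb, cell_px, axis=0), cell_px, axis=1)
    return Image.fromarray(rgb, mode="RGB")


# ---------------------------------------------------------------------------
# sequence space

def render_sequence_space(emb: Embedding,
                          annotations: AnnotationTable | None = None,
                          color_key: str | None = None,
                          ids: list[str] | None = None):
    """Scatter of the embedding; 3-D embeddings are shown as two projections.

    A categorical annotation gives a discrete legend, a numeric one a
    continuous colorbar; sequences missing the annotation are drawn gray.
    """
    coords = emb.coords
    dims = coords.shape[1]
    panels = [(0, 1)] if dims == 2 else [(0, 1), (0, 2)]
    fig, axes = plt.subplots(1, len(panels), figsize=(5.5 * len(panels), 5),
                             squeeze=False)
    axes = axes[0]

    values = None
    if color_key is not None:
        if annotations is None or color_key not in annotations.columns:
            raise KeyError(f"annotation {color_key!r} not found")
        if ids is None:
            raise ValueError("ids are required to look up annotation values")
        values = annotations.values_for(color_key, ids)

    for ax, (dx, dy) in zip(axes, panels):
        if values is None:
            ax.scatter(coords[:, dx], coords[:, dy], s=12, color="#4070b0",
                       edgecolors="none")
        elif annotations.is_numeric(color_key):
            missing = values.isna().to_numpy()
            sc = ax.scatter(coords[~missing, dx], coords[~missing, dy], s=12,
                            c=values.to_numpy()[~missing], cmap="viridis",
                            edgecolors="none")
            ax.scatter(coords[missing, dx], coords[missing, dy], s=12,
                       color="0.6", edgecolors="none")
            fig.colorbar(sc, ax=ax, label=color_key)
        else:
            cats = sorted(values.dropna().unique())
            cycle = plt.rcParams["axes.prop_cycle"].by_key()["color"]
            for c, cat in enumerate(cats):
                sel = (values == cat).to_numpy()
                ax.scatter(coords[sel, dx], coords[sel, dy], s=12,
                           color=cycle[c % len(cycle)], label=str(cat),
                           edgecolors="none")
            missing = values.isna().to_numpy()
            if missing.any():
                ax.scatter(coords[missing, dx], coords[missing, dy], s=12,
                           color="0.6", label="(missing)", edgecolors="none")
            ax.legend(frameon=False, fontsize=8)
        ax.set_xlabel(f"UMAP {dx + 1}")
        ax.set_ylabel(f"UMAP {dy + 1}")
    fig.tight_layout()
    return fig
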