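"""Unit-cube mapping of species GC triples and renderer-agnostic export.

Each species' (GC%_DNA, GC%_cDNA, GC%_cds) triple becomes a point in the
unit cube [0,1]³ with the conventional red/green/blue axis assignment:
x (red) ← DNA, y (green) ← cDNA, z (blue) ← cds. Two normalization modes
are offered: ``fixed_0_100`` divides by 100 (comparable across datasets)
and ``minmax_per_axis`` stretches each axis over the observed range. The
mode and the axis ranges are stored in the exported bundle so coordinates
can be denormalized losslessly. An optional newick tree is passed through
for renderers that draw the phylogeny in the bottom plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import dendropy

from . import schemas
from .profiles import SpeciesProfile

__all__ = [
    "CubeCoordinate",
    "VisualizationBundle",
    "DEFAULT_PALETTE_CYCLE",
    "make_abbreviation",
    "assign_palette",
    "normalize_to_cube",
    "denormalize",
    "export_bundle",
    "load_bundle",
    "plot_cube",
]

AXES = ("x", "y", "z")  # x←DNA (red), y←cDNA (green), z←cds (blue)

#: Deterministic group-color cycle (matplotlib tab10 hex values).
DEFAULT_PALETTE_CYCLE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


@dataclass(frozen=True)
class CubeCoordinate:
    """One species placed in the unit cube, with its group color."""

    species: str
    abbreviation: str
    group: str
    x: float
    y: float
    z: float
    color: str

    def __post_init__(self) -> None:
        for a in AXES:
            v = getattr(self, a)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.species}: {a}={v} outside [0, 1]")


@dataclass(frozen=True)
class VisualizationBundle:
    """Everything a renderer needs: points, ranges, palette, optional tree."""

    coordinates: tuple[CubeCoordinate, ...]
    axis_ranges: dict[str, tuple[float, float]]
    palette: dict[str, str]
    mode: str
    tree: str | None = None
    warnings: tuple[str, ...] = ()


def make_abbreviation(species: str) -> str:
    """Sphere label: first letter of genus + first three of the epithet.

    "Danio rerio" → "Drer"; single-token names are truncated to 4 chars.
    """
    tokens = species.replace("_", " ").split()
    if len(tokens) >= 2:
        return tokens[0][0].upper() + tokens[1][:3].lower()
    return tokens[0][:4].capitalize()


def _dedup_abbreviations(abbrs: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for a in abbrs:
        if a in seen:
            seen[a] += 1
            out.append(f"{a}{seen[a]}")
        else:
            seen[a] = 0
            out.append(a)
    return out


def assign_palette(groups: list[str]) -> dict[str, str]:
    """Stable group→color map: colors assigned in sorted-group order."""
    return {
        g: DEFAULT_PALETTE_CYCLE[i % len(DEFAULT_PALETTE_CYCLE)]
        for i, g in enumerate(sorted(set(groups)))
    }


def normalize_to_cube(
    profiles: list[SpeciesProfile],
    mode: str = "fixed_0_100",
    ranges: dict[str, tuple[float, float]] | None = None,
    palette: dict[str, str] | None = None,
) -> tuple[list[CubeCoordinate], dict[str, tuple[float, float]]]:
    """Map GC triples into [0,1]³; returns (coordinates, axis_ranges used).

    ``fixed_0_100`` uses (0, 100) on every axis; ``minmax_per_axis`` uses
    each axis's observed min/max (error on zero spread); explicit ``ranges``
    override either. Mapping is (gc − lo)/(hi − lo) clamped to [0,1] and is
    order-preserving per axis.
    """
    if mode not in ("fixed_0_100", "minmax_per_axis"):
        raise ValueError(f"unknown mode {mode!r}")
    if not profiles:
        raise ValueError("no profiles to normalize")
    per_axis = {
        "x": [p.gc_dna for p in profiles],
        "y": [p.gc_cdna for p in profiles],
        "z": [p.gc_cds for p in profiles],
    }
    if ranges is None:
        if mode == "fixed_0_100":
            ranges = {a: (0.0, 100.0) for a in AXES}
        else:
            ranges = {a: (min(v), max(v)) for a, v in per_axis.items()}
    for a in AXES:
        lo, hi = ranges[a]
        if hi <= lo:
            raise ValueError(f"degenerate axis {a}: range ({lo}, {hi})")
    palette = palette or assign_palette([p.group for p in profiles])
    abbrs = _dedup_abbreviations(
        [p.abbreviation or make_abbreviation(p.species) for p in profiles]
    )
    coords = []
    for p, abbr in zip(profiles, abbrs):
        point = {}
        for a, gc in zip(AXES, p.triple):
            lo, hi = ranges[a]
            point[a] = min(1.0, max(0.0, (gc - lo) / (hi - lo)))
        coords.append(
            CubeCoordinate(
                species=p.species, abbreviation=abbr, group=p.group,
                color=palette[p.group], **point,
            )
        )
    return coords, {a: (float(lo), float(hi)) for a, (lo, hi) in ranges.items()}


def denormalize(
    coord: CubeCoordinate, axis_ranges: dict[str, tuple[float, float]]
) -> tuple[float, float, float]:
    """Invert the cube mapping back to a (DNA, cDNA, cds) GC% triple."""
    out = []
    for a in AXES:
        lo, hi = axis_ranges[a]
        out.append(lo + getattr(coord, a) * (hi - lo))
    return tuple(out)


def _tree_leaf_warnings(coords: list[CubeCoordinate], tree: str) -> list[str]:
    t = dendropy.Tree.get(data=tree, schema="newick")
    leaves = {lf.taxon.label.replace("_", " ") for lf in t.leaf_node_iter() if lf.taxon}
    missing = sorted(
        c.species for c in coords if c.species.replace("_", " ") not in leaves
    )
    return [f"species not among tree leaves: {s}" for s in missing]


def export_bundle(
    coords: list[CubeCoordinate],
    path: str | Path,
    *,
    axis_ranges: dict[str, tuple[float, float]] | None = None,
    mode: str = "fixed_0_100",
    tree: str | None = None,
) -> VisualizationBundle:
    """Write the visualization bundle JSON; returns the in-memory bundle.

    The bundle validates against :data:`schemas.BUNDLE_SCHEMA` and
    round-trips losslessly via :func:`load_bundle`. Duplicate species are an
    error; species absent from the tree's leaf set are recorded as warnings
    in the bundle, not errors.
    """
    if not coords:
        raise ValueError("no coordinates to export")
    names = [c.species for c in coords]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate species in coordinates: {dupes}")
    axis_ranges = axis_ranges or {a: (0.0, 100.0) for a in AXES}
    palette = {c.group: c.color for c in coords}
    warns = _tree_leaf_warnings(coords, tree) if tree else []
    bundle = VisualizationBundle(
        coordinates=tuple(coords),
        axis_ranges={a: tuple(axis_ranges[a]) for a in AXES},
        palette=palette,
        mode=mode,
        tree=tree,
        warnings=tuple(warns),
    )
    doc: dict = {
        "mode": bundle.mode,
        "axis_ranges": {a: list(bundle.axis_ranges[a]) for a in AXES},
        "palette": dict(sorted(bundle.palette.items())),
        "coordinates": [
            {
                "species": c.species, "abbreviation": c.abbreviation,
                "group": c.group, "x": c.x, "y": c.y, "z": c.z, "color": c.color,
            }
            for c in bundle.coordinates
        ],
    }
    if tree is not None:
        doc["tree"] = tree
    if warns:
        doc["warnings"] = warns
    schemas.validate(doc, schemas.BUNDLE_SCHEMA)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return bundle


def load_bundle(path: str | Path) -> VisualizationBundle:
    """Read and validate a bundle written by :func:`export_bundle`."""
    doc = json.loads(Path(path).read_text())
    schemas.validate(doc, schemas.BUNDLE_SCHEMA)
    coords = tuple(CubeCoordinate(**c) for c in doc["coordinates"])
    return VisualizationBundle(
        coordinates=coords,
        axis_ranges={a: tuple(doc["axis_ranges"][a]) for a in AXES},
        palette=doc["palette"],
        mode=doc["mode"],
        tree=doc.get("tree"),
        warnings=tuple(doc.get("warnings", ())),
    )


def plot_cube(bundle: VisualizationBundle, path: str | Path | None = None):
    """Static 3D scatter of the bundle (matplotlib); returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for c in bundle.coordinates:
        ax.scatter(c.x, c.y, c.z, color=c.color, s=30)
        ax.text(c.x, c.y, c.z, c.abbreviation, fontsize=6)
    ax.set_xlabel("DNA (red axis)")
    ax.set_ylabel("cDNA (green axis)")
    ax.set_zlabel("cds (blue axis)")
    ax.set_xlim(0, 1), ax.set_ylim(0, 1), ax.set_zlim(0, 1)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
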