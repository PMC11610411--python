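"""Richness maps and species-discovery / nomenclatural-change analytics.

Two families of outputs:

* **Richness choropleths** — per-region counts of distinct accepted
  species, at the political-country or botanical-country level, drawn on
  user-supplied region polygons (GeoJSON whose features carry a
  ``region_name`` property joining to the count table). A species
  occurring in three regions adds one to each of the three, never three
  to one. Species with no resolvable region are excluded from the map
  but always reported in ``unknown_count``. Colour scales default to
  perceptually uniform, colour-vision-deficiency-safe matplotlib
  palettes (viridis family).

* **Discovery analytics** — cumulative species counts against
  publication year, under two date bases. The *accepted-date* basis uses
  the publication year of the currently accepted name; the
  *basionym-date* basis uses the earliest homotypic year, which dates the
  actual first description of the species and thus discounts purely
  nomenclatural recombination. Since a basionym can only precede its
  recombination, the basionym-basis curve lies on or above the
  accepted-basis curve at every year. A companion change table pairs each
  accepted name with the years and kinds (homotypic/heterotypic) of its
  synonyms, feeding the per-year "violin" view of nomenclatural churn.

Renderers are pure functions of their input tables and write a plot-data
sidecar CSV next to each image, so the plotted numbers are testable
without comparing pixels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PatchCollection
from matplotlib.patches import PathPatch
from matplotlib.path import Path as MplPath
from shapely.geometry import shape

from .model import NOMENCLATURE_START, SpeciesRecord, basionym_year

__all__ = [
    "COUNTRY_LEVEL",
    "BOTANICAL_LEVEL",
    "ACCEPTED_BASIS",
    "BASIONYM_BASIS",
    "RichnessTable",
    "AccumulationSeries",
    "ChangeRow",
    "NomenclaturalChangeTable",
    "MapRender",
    "GraphRender",
    "richness_table",
    "richness_by_group",
    "render_richness_map",
    "render_grouped_maps",
    "accumulation_series",
    "nomenclatural_change_table",
    "render_discovery_graph",
]

COUNTRY_LEVEL = "country"
BOTANICAL_LEVEL = "botanical_country"
ACCEPTED_BASIS = "accepted_date"
BASIONYM_BASIS = "basionym_date"


@dataclass
class RichnessTable:
    """Per-region distinct accepted-species counts at one level."""

    level: str
    counts: dict = field(default_factory=dict)
    unknown_count: int = 0

    @property
    def total_incidences(self) -> int:
        return sum(self.counts.values())


def _regions_of(ann, level: str, use_introduced: bool) -> set[str]:
    sp = ann.species if hasattr(ann, "species") else ann
    if level == BOTANICAL_LEVEL:
        regions = set(sp.distribution.native_botanical)
        if use_introduced:
            regions |= sp.distribution.introduced_botanical
    elif level == COUNTRY_LEVEL:
        if not hasattr(ann, "countries"):
            raise ValueError(
                "country-level richness needs annotated records "
                "(attach_country_distribution)"
            )
        regions = set(ann.countries.native_countries)
        if use_introduced:
            regions |= ann.countries.introduced_countries
    else:
        raise ValueError(f"unknown level {level!r}")
    return regions


def richness_table(annotated, level: str = COUNTRY_LEVEL, use_introduced: bool = False) -> RichnessTable:
    """Count distinct accepted species per region.

    Native ranges only, unless ``use_introduced``. Species contributing
    to no region at this level (unknown distribution, or none of its
    botanical countries resolved) are tallied in ``unknown_count``.
    """
    table = RichnessTable(level=level)
    for ann in annotated:
        regions = _regions_of(ann, level, use_introduced)
        if not regions:
            table.unknown_count += 1
            continue
        for region in regions:
            table.counts[region] = table.counts.get(region, 0) + 1
    return table


def richness_by_group(annotated, group, level: str = COUNTRY_LEVEL, use_introduced: bool = False) -> dict:
    """One richness table per group label (e.g. per family).

    ``group`` is an attribute name of the species record (``"family"``)
    or a callable on the annotated record. Unknown attribute names raise
    immediately, naming the attribute.
    """
    keyfn = _group_keyfn(group)
    grouped: dict[str, list] = {}
    for ann in annotated:
        grouped.setdefault(keyfn(ann), []).append(ann)
    return {
        label: richness_table(members, level, use_introduced)
        for label, members in sorted(grouped.items())
    }


def _group_keyfn(group):
    if callable(group):
        return group
    if isinstance(group, str):
        def keyfn(ann):
            sp = ann.species if hasattr(ann, "species") else ann
            if not hasattr(sp, group):
                raise KeyError(f"unknown grouping column {group!r} on species records")
            return getattr(sp, group)
        return keyfn
    raise TypeError(f"group must be a str or callable, got {type(group)!r}")


# ---------------------------------------------------------------------------
# Choropleth rendering


@dataclass
class MapRender:
    path: Path
    unmatched: set = field(default_factory=set)
    sidecar: Path | None = None


def _load_geometries(geometries) -> dict[str, object]:
    """GeoJSON (path or parsed dict) → {region_name: shapely geometry}."""
    if isinstance(geometries, (str, Path)):
        with open(geometries, encoding="utf-8") as fh:
            geometries = json.load(fh)
    out = {}
    for feature in geometries.get("features", []):
        name = (feature.get("properties") or {}).get("region_name")
        if name:
            out[name] = shape(feature["geometry"])
    return out


def _polygon_patches(geom):
    polys = getattr(geom, "geoms", [geom])
    for poly in polys:
        vertices = list(poly.exterior.coords)
        codes = [MplPath.MOVETO] + [MplPath.LINETO] * (len(vertices) - 2) + [MplPath.CLOSEPOLY]
        for interior in poly.interiors:
            ring = list(interior.coords)
            vertices += ring
            codes += [MplPath.MOVETO] + [MplPath.LINETO] * (len(ring) - 2) + [MplPath.CLOSEPOLY]
        yield PathPatch(MplPath(vertices, codes))


def render_richness_map(
    table: RichnessTable,
    geometries,
    out_path: str | Path,
    palette: str = "viridis",
    group_label: str | None = None,
    title: str | None = None,
) -> MapRender:
    """Draw a richness choropleth and its plot-data sidecar CSV.

    Regions with no data take a neutral grey fill; counted regions with
    no geometry are reported in ``unmatched`` (and in the sidecar), never
    silently dropped. With ``group_label``, the label is suffixed to the
    file stem so per-group maps of one run land side by side.
    """
    out_path = Path(out_path)
    if group_label:
        out_path = out_path.with_name(
            f"{out_path.stem}_{group_label.replace(' ', '_')}{out_path.suffix}"
        )
    out_path.parent.mkdir(parents=True, exist_ok=True)
    geoms = _load_geometries(geometries)
    unmatched = {r for r in table.counts if r not in geoms}

    fig, ax = plt.subplots(figsize=(10, 6))
    cmap = plt.get_cmap(palette)
    max_count = max(table.counts.values(), default=1)
    norm = matplotlib.colors.Normalize(vmin=0, vmax=max_count)
    for name, geom in sorted(geoms.items()):
        count = table.counts.get(name)
        color = cmap(norm(count)) if count is not None else (0.85, 0.85, 0.85, 1.0)
        patches = list(_polygon_patches(geom))
        ax.add_collection(
            PatchCollection(patches, facecolor=color, edgecolor="white", linewidth=0.4)
        )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.colorbar(
        matplotlib.cm.ScalarMappable(norm=norm, cmap=cmap),
        ax=ax, shrink=0.6, label="accepted species",
    )
    ax.set_title(title or (f"Species richness — {group_label}" if group_label else "Species richness"))
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    sidecar = out_path.with_suffix(".csv")
    with open(sidecar, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["region", "count", "has_geometry"])
        for region in sorted(table.counts):
            writer.writerow([region, table.counts[region], str(region in geoms).lower()])
        writer.writerow(["__unknown__", table.unknown_count, ""])
    return MapRender(path=out_path, unmatched=unmatched, sidecar=sidecar)


def render_grouped_maps(
    tables: dict, geometries, out_path: str | Path, palette: str = "viridis"
) -> list[MapRender]:
    """One choropleth per group table (the per-taxon multi-map mode)."""
    return [
        render_richness_map(table, geometries, out_path, palette, group_label=label)
        for label, table in sorted(tables.items())
    ]


# ---------------------------------------------------------------------------
# Discovery accumulation and nomenclatural change


@dataclass
class AccumulationSeries:
    """Cumulative accepted-species count per publication year."""

    basis: str
    points: tuple = ()  # sorted (year, cumulative count)
    n_unknown_year: int = 0

    @property
    def final_count(self) -> int:
        return self.points[-1][1] if self.points else 0

    def value_at(self, year: int) -> int:
        count = 0
        for y, c in self.points:
            if y > year:
                break
            count = c
        return count


def _basis_year(sp: SpeciesRecord, basis: str) -> int | None:
    if basis == ACCEPTED_BASIS:
        return sp.accepted.year
    if basis == BASIONYM_BASIS:
        return basionym_year(sp)
    raise ValueError(f"unknown date basis {basis!r}")


def accumulation_series(species, basis: str = ACCEPTED_BASIS) -> AccumulationSeries:
    """Species-discovery accumulation curve under the given date basis.

    Species whose basis year is unknown are excluded from the curve and
    tallied in ``n_unknown_year``, so the final cumulative count plus the
    unknown tally always equals the total species count.
    """
    records = [sp.species if hasattr(sp, "species") else sp for sp in species]
    years = []
    unknown = 0
    for sp in records:
        y = _basis_year(sp, basis)
        if y is None:
            unknown += 1
        else:
            years.append(y)
    years.sort()
    points = []
    for i, y in enumerate(years, start=1):
        if points and points[-1][0] == y:
            points[-1] = (y, i)
        else:
            points.append((y, i))
    return AccumulationSeries(basis=basis, points=tuple(points), n_unknown_year=unknown)


@dataclass(frozen=True)
class ChangeRow:
    binomial: str
    accepted_year: int | None
    synonyms: tuple  # of (year-or-None, "homotypic"|"heterotypic")
    group: str = ""

    @property
    def n_synonyms(self) -> int:
        return len(self.synonyms)


@dataclass
class NomenclaturalChangeTable:
    rows: tuple = ()

    @property
    def total_synonyms(self) -> int:
        return sum(r.n_synonyms for r in self.rows)

    def groups(self) -> list[str]:
        return sorted({r.group for r in self.rows})


_STATUS_SHORT = {"homotypic_synonym": "homotypic", "heterotypic_synonym": "heterotypic"}


def nomenclatural_change_table(species, group=None) -> NomenclaturalChangeTable:
    """Pair each accepted name's year with its synonyms' years and kinds.

    ``group`` (an attribute name such as ``"family"``, or a callable)
    adds a faceting label for per-group plots; an unknown attribute name
    raises a named error.
    """
    keyfn = _group_keyfn(group) if group is not None else (lambda ann: "")
    rows = []
    for item in species:
        sp = item.species if hasattr(item, "species") else item
        rows.append(
            ChangeRow(
                binomial=sp.binomial,
                accepted_year=sp.accepted.year,
                synonyms=tuple(
                    (s.year, _STATUS_SHORT.get(s.status, s.status)) for s in sp.synonyms
                ),
                group=keyfn(item),
            )
        )
    return NomenclaturalChangeTable(rows=tuple(rows))


@dataclass
class GraphRender:
    curves_path: Path
    violin_path: Path
    curves_sidecar: Path
    changes_sidecar: Path


def _write_curves_sidecar(path: Path, series_list) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["basis", "year", "cumulative_species", "n_unknown_year"])
        for series in series_list:
            for year, count in series.points:
                writer.writerow([series.basis, year, count, series.n_unknown_year])


def _write_changes_sidecar(path: Path, table: NomenclaturalChangeTable) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["group", "binomial", "accepted_year", "synonym_year", "synonym_kind"])
        for row in table.rows:
            if not row.synonyms:
                writer.writerow([row.group, row.binomial, row.accepted_year or "", "", ""])
            for year, kind in row.synonyms:
                writer.writerow([row.group, row.binomial, row.accepted_year or "", year or "", kind])


def render_discovery_graph(
    accepted_series: AccumulationSeries,
    basionym_series: AccumulationSeries,
    change_table: NomenclaturalChangeTable,
    out_dir: str | Path,
    basename: str = "discovery",
) -> GraphRender:
    """Write the dual accumulation-curve figure and the change "violin".

    Curves: accepted-name basis in black, basionym basis in red (the
    basionym curve can only run on or above the other). Violin panel:
    per-group distribution of accepted-name publication years, with each
    accepted name overplotted at its year, sized by its synonym count.
    The x axis is clipped to [1753, latest year present]. Plot data go to
    sidecar CSVs so the figures are reproducible and testable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves_path = out_dir / f"{basename}_curves.png"
    violin_path = out_dir / f"{basename}_changes.png"

    latest = NOMENCLATURE_START
    for series in (accepted_series, basionym_series):
        if series.points:
            latest = max(latest, series.points[-1][0])
    known_years = [r.accepted_year for r in change_table.rows if r.accepted_year]
    if known_years:
        latest = max(latest, max(known_years))
    latest = max(latest, NOMENCLATURE_START + 1)  # degenerate single-year input

    fig, ax = plt.subplots(figsize=(8, 5))
    for series, color, label in (
        (accepted_series, "black", "accepted-name date"),
        (basionym_series, "firebrick", "basionym date"),
    ):
        if series.points:
            xs = [y for y, _ in series.points]
            ys = [c for _, c in series.points]
            ax.step([NOMENCLATURE_START] + xs, [0] + ys, where="post", color=color, label=label)
    ax.set_xlim(NOMENCLATURE_START, latest)
    ax.set_xlabel("year of publication")
    ax.set_ylabel("cumulative accepted species")
    ax.legend(loc="upper left")
    fig.savefig(curves_path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 5))
    groups = change_table.groups() or [""]
    for i, group in enumerate(groups):
        rows = [r for r in change_table.rows if r.group == group and r.accepted_year]
        years = np.array([r.accepted_year for r in rows], dtype=float)
        if len(years) > 1 and years.std() > 0:
            ax.violinplot(
                [years], positions=[i], orientation="horizontal",
                widths=0.8, showextrema=False,
            )
        sizes = np.array([10 + 25 * r.n_synonyms for r in rows])
        jitter = (np.arange(len(rows)) % 7 - 3) * 0.04
        ax.scatter(years, np.full(len(rows), i) + jitter, s=sizes,
                   color="goldenrod", edgecolor="gray", alpha=0.7, zorder=3)
    ax.set_yticks(range(len(groups)))
    ax.set_yticklabels([g or "all" for g in groups])
    ax.set_xlim(NOMENCLATURE_START, latest)
    ax.set_xlabel("accepted-name publication year (point size ∝ synonyms)")
    fig.savefig(violin_path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    curves_sidecar = out_dir / f"{basename}_curves.csv"
    changes_sidecar = out_dir / f"{basename}_changes.csv"
    _write_curves_sidecar(curves_sidecar, [accepted_series, basionym_series])
    _write_changes_sidecar(changes_sidecar, change_table)
    return GraphRender(curves_path, violin_path, curves_sidecar, changes_sidecar)
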