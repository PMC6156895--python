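"""Annotation-defined probe regions.

Instead of growing regions by genomic distance, probes are grouped by
fixed biological annotation: six gene functional categories (TSS1500,
TSS200, 5'UTR, 1stExon, Body, 3'UTR — subregions of a gene's UCSC
annotation) and five CpG-island relation categories (Island, N_Shore,
S_Shore, N_Shelf, S_Shelf; shores lie within 2 kb of an island, shelves
within 2 kb of a shore).  A region is one distinct (name, category)
pair; its bounds are the min/max position of its member probes.  The
same probe may belong to several regions — annotations overlap, which
is why the region family is FDR- rather than Bonferroni-corrected
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ProbeManifest, ISLAND_RELATIONS

__all__ = ["GENE_CATEGORIES", "ISLAND_CATEGORIES", "AnnotationRegion",
           "RegionSet", "build_gene_regions", "build_island_regions",
           "attach_regions", "write_regions", "read_regions"]

GENE_CATEGORIES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")
ISLAND_CATEGORIES = ISLAND_RELATIONS

_GENE_ALIASES = {c.lower(): c for c in GENE_CATEGORIES}
_GENE_ALIASES["5utr"] = "5'UTR"
_GENE_ALIASES["3utr"] = "3'UTR"


@dataclass(frozen=True)
class AnnotationRegion:
    """A named probe set from one annotation category.

    ``probe_ids`` are unique and ordered by genomic position (probe id
    as tie-break); all probes share a chromosome; ``start``/``stop`` are
    the min/max probe positions (1-based inclusive).
    """

    region_id: str
    name: str
    category: str
    chrom: str
    start: int
    stop: int
    probe_ids: tuple
    positions: tuple = ()  # per-probe positions parallel to probe_ids (optional)

    @property
    def m(self) -> int:
        """Number of member probes."""
        return len(self.probe_ids)

    def probe_positions(self, probe_ids) -> list[int]:
        """Positions of a subset of member probes (region bounds if unknown)."""
        if len(self.positions) == len(self.probe_ids):
            lookup = dict(zip(self.probe_ids, self.positions))
            return [int(lookup[p]) for p in probe_ids]
        return [self.start, self.stop]


class RegionSet:
    """Regions keyed by region_id, plus a probe -> region_ids inverted index."""

    def __init__(self, regions: Iterable[AnnotationRegion] = ()):
        self.regions: dict[str, AnnotationRegion] = {}
        self.probe_index: dict[str, list[str]] = defaultdict(list)
        for r in regions:
            self.add(r)

    def add(self, region: AnnotationRegion) -> None:
        if region.region_id in self.regions:
            raise ValueError(f"duplicate region id {region.region_id!r}")
        if len(set(region.probe_ids)) != len(region.probe_ids):
            raise ValueError(f"region {region.region_id!r} lists a probe twice")
        self.regions[region.region_id] = region
        for p in region.probe_ids:
            self.probe_index[p].append(region.region_id)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions.values())

    def __contains__(self, region_id: str) -> bool:
        return region_id in self.regions

    def __getitem__(self, region_id: str) -> AnnotationRegion:
        return self.regions[region_id]

    def sorted_ids(self) -> list[str]:
        return sorted(self.regions)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"region_id": r.region_id, "category": r.category, "chrom": r.chrom,
             "start": r.start, "stop": r.stop, "m": r.m,
             "probe_ids": ";".join(r.probe_ids)}
            for rid, r in sorted(self.regions.items())
        ]
        return pd.DataFrame(rows, columns=["region_id", "category", "chrom",
                                           "start", "stop", "m", "probe_ids"])


def _make_regions(groups: dict, manifest: ProbeManifest) -> list[AnnotationRegion]:
    """Assemble regions from {(name, category): set(probe_id)} groups.

    A (name, category) pair whose probes span several chromosomes is
    split per chromosome with the chromosome appended to the region id
    (annotation names are normally chromosome-specific, so this is a
    manifest oddity, not the common path).
    """
    pos = manifest.data["pos"]
    chrom = manifest.data["chrom"]
    out = []
    for (name, category), probes in sorted(groups.items()):
        by_chrom: dict[str, list[str]] = defaultdict(list)
        for p in probes:
            by_chrom[chrom.loc[p]].append(p)
        split = len(by_chrom) > 1
        for ch, plist in sorted(by_chrom.items()):
            ordered = tuple(sorted(plist, key=lambda p: (int(pos.loc[p]), p)))
            positions = tuple(int(pos.loc[p]) for p in ordered)
            rid = f"{name}:{category}" + (f":{ch}" if split else "")
            out.append(AnnotationRegion(rid, name, category, str(ch),
                                        min(positions), max(positions), ordered,
                                        positions))
    return out


def build_gene_regions(manifest: ProbeManifest, retained=None) -> tuple[RegionSet, dict]:
    """One region per distinct (gene, functional category) pair.

    Gene name and group tokens are paired strictly positionally across
    the two semicolon lists (manifest convention); duplicate pairs within
    one probe contribute a single membership.  Unknown category tokens
    are skipped and counted in the audit.  Only ``retained`` probes (all
    if None) are considered.
    """
    keep = set(map(str, retained)) if retained is not None else None
    groups: dict[tuple, set] = defaultdict(set)
    skipped_tokens = 0
    for pid, names, cats in zip(manifest.data.index, manifest.data["gene_names"],
                                manifest.data["gene_groups"]):
        if keep is not None and pid not in keep:
            continue
        for name, cat in zip(names, cats):
            norm = _GENE_ALIASES.get(cat.strip().lower().replace("'", "").replace("_", ""))
            if norm is None:
                norm = _GENE_ALIASES.get(cat.strip().lower())
            if norm is None:
                skipped_tokens += 1
                continue
            groups[(name, norm)].add(pid)
    regions = _make_regions(groups, manifest)
    audit = {"n_regions": len(regions), "skipped_category_tokens": skipped_tokens}
    return RegionSet(regions), audit


def build_island_regions(manifest: ProbeManifest, retained=None) -> tuple[RegionSet, dict]:
    """One region per distinct (island name, relation) pair.

    Probes with relation 'none' belong to no island region; a probe with
    a relation but no island name is skipped with an audit count.  North
    and south shores/shelves of one island are distinct regions.
    """
    keep = set(map(str, retained)) if retained is not None else None
    groups: dict[tuple, set] = defaultdict(set)
    skipped_unnamed = 0
    for pid, name, rel in zip(manifest.data.index, manifest.data["island_name"],
                              manifest.data["island_relation"]):
        if keep is not None and pid not in keep:
            continue
        if rel == "none":
            continue
        if not name:
            skipped_unnamed += 1
            continue
        groups[(name, rel)].add(pid)
    regions = _make_regions(groups, manifest)
    audit = {"n_regions": len(regions), "skipped_unnamed_probes": skipped_unnamed}
    return RegionSet(regions), audit


def attach_regions(gene_set: RegionSet, island_set: RegionSet,
                   min_probes: int = 2, max_probes: int | None = None) -> tuple[RegionSet, dict]:
    """Union of gene and island regions, filtered by probe count.

    Regions with fewer than ``min_probes`` or more than ``max_probes``
    members are dropped (single-probe regions duplicate the per-probe
    EWAS, hence the default minimum of 2).  Overlap between the two sets
    is preserved: the same probes may drive both a gene region and an
    island region.
    """
    if max_probes is not None and min_probes > max_probes:
        raise ValueError(f"min_probes ({min_probes}) > max_probes ({max_probes})")
    hi = max_probes if max_probes is not None else np.inf
    out = RegionSet()
    dropped = 0
    for rs in (gene_set, island_set):
        for r in rs:
            if min_probes <= r.m <= hi:
                out.add(r)
            else:
                dropped += 1
    audit = {"n_regions": len(out),
             "n_before_size_filter": len(gene_set) + len(island_set),
             "dropped_by_size": dropped}
    return out, audit


def write_regions(regions: RegionSet, path: str) -> None:
    """Region dump TSV, consumable back as a custom region file."""
    regions.to_table().to_csv(path, sep="\t", index=False)


def read_regions(path: str) -> RegionSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = RegionSet()
    for row in df.itertuples():
        probes = tuple(str(row.probe_ids).split(";"))
        name = row.region_id.rsplit(":", 1)[0] if ":" in row.region_id else row.region_id
        out.add(AnnotationRegion(str(row.region_id), name, str(row.category),
                                 str(row.chrom), int(row.start), int(row.stop), probes))
    return out
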