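"""PTM sites and merged PTM regions.

A PTM region is a post-translationally modified residue plus ±7 flanking
residues, with overlapping windows merged, capturing the short linear motifs
that reader/writer/eraser enzymes recognise. Residues within a region are
labelled by distance to the nearest modified residue (DI: the modified
residue itself; N1: proximal flank, 1-2 residues; N2: distal flank, 3-7
residues) and by the number of modified residues within ±7 (cluster bins
1..5+).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_FLANK = 7

#: amino acids each modification type can occur on
PTM_ALLOWED_RESIDUES: dict[str, frozenset[str]] = {
    "phospho": frozenset("STY"),
    "ubiq": frozenset("K"),
    "acet": frozenset("K"),
    "methyl": frozenset("KR"),
}

PTM_TYPES = tuple(PTM_ALLOWED_RESIDUES)

#: zone labels by distance to the nearest modified residue
ZONE_DI, ZONE_N1, ZONE_N2 = "DI", "N1", "N2"

CLUSTER_CAP = 5  # bins 1..4 then "5+"


@dataclass(frozen=True)
class PTMSite:
    """One experimentally observed modified residue."""

    protein: str
    position: int  # 1-based residue index
    residue: str
    ptm_type: str
    n_pubs: int = 1
    enzymes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.ptm_type not in PTM_ALLOWED_RESIDUES:
            raise ValueError(f"unknown PTM type {self.ptm_type!r}")
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")


@dataclass
class PTMRegion:
    """Maximal merged interval of overlapping ±flank windows around sites."""

    protein: str
    start: int  # 1-based closed interval
    end: int
    sites: list[PTMSite] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def site_positions(self) -> list[int]:
        # one DI residue per position even if several PTM types hit it
        return sorted({s.position for s in self.sites})

    @property
    def types(self) -> set[str]:
        return {s.ptm_type for s in self.sites}


def validate_site(site: PTMSite, sequence: str | None = None) -> None:
    allowed = PTM_ALLOWED_RESIDUES[site.ptm_type]
    if site.residue not in allowed:
        raise ValueError(
            f"{site.protein}:{site.position} residue {site.residue!r} not in "
            f"allowed set {sorted(allowed)} for {site.ptm_type}"
        )
    if sequence is not None:
        if site.position > len(sequence):
            raise ValueError(f"{site.protein}:{site.position} beyond sequence length {len(sequence)}")
        if sequence[site.position - 1] != site.residue:
            raise ValueError(
                f"{site.protein}:{site.position} sequence has "
                f"{sequence[site.position - 1]!r}, site claims {site.residue!r}"
            )


def match_peptides(
    peptides: Iterable[tuple],
    proteome: Mapping[str, str],
) -> tuple[list[PTMSite], list[dict]]:
    """Match modification peptides to a proteome by exact substring search.

    Each peptide record is ``(peptide, ptm_type)`` or ``(peptide, ptm_type,
    n_pubs)``; the modified residue is the centre of the odd-length peptide
    (15-mers in the source databases). Every exact occurrence in any protein
    yields one site; multiple matches per sequence are allowed. Returns the
    matched sites and a list of rejection/no-match reports.
    """
    sites: list[PTMSite] = []
    rejected: list[dict] = []
    for rec in peptides:
        pep, ptm_type = rec[0], rec[1]
        n_pubs = rec[2] if len(rec) > 2 else 1
        if len(pep) % 2 == 0 or len(pep) > 15:
            rejected.append({"peptide": pep, "reason": "peptide must be odd-length <=15"})
            continue
        center = len(pep) // 2
        residue = pep[center]
        if ptm_type not in PTM_ALLOWED_RESIDUES:
            rejected.append({"peptide": pep, "reason": f"unknown PTM type {ptm_type!r}"})
            continue
        if residue not in PTM_ALLOWED_RESIDUES[ptm_type]:
            rejected.append(
                {"peptide": pep, "reason": f"center residue {residue!r} incompatible with {ptm_type}"}
            )
            continue
        n_found = 0
        for name, seq in proteome.items():
            at = seq.find(pep)
            while at != -1:
                sites.append(PTMSite(name, at + center + 1, residue, ptm_type, n_pubs))
                n_found += 1
                at = seq.find(pep, at + 1)
        if n_found == 0:
            rejected.append({"peptide": pep, "reason": "no match in proteome"})
    return sites, rejected


def build_regions(
    sites: Sequence[PTMSite],
    protein_lengths: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
) -> list[PTMRegion]:
    """Merge per-site ±flank windows into maximal PTM regions.

    Windows are clipped to [1, protein length]; windows sharing at least one
    residue are merged (strictly adjacent but disjoint windows stay
    separate). Regions are returned sorted by (protein, start).
    """
    by_protein: dict[str, list[PTMSite]] = {}
    for s in sites:
        by_protein.setdefault(s.protein, []).append(s)
    regions: list[PTMRegion] = []
    for protein in sorted(by_protein):
        length = protein_lengths[protein]
        plist = sorted(by_protein[protein], key=lambda s: s.position)
        current: PTMRegion | None = None
        for s in plist:
            lo = max(1, s.position - flank)
            hi = min(length, s.position + flank)
            if current is not None and lo <= current.end:
                current.end = max(current.end, hi)
                current.sites.append(s)
            else:
                current = PTMRegion(protein, lo, hi, [s])
                regions.append(current)
    return regions


def classify_zones(region: PTMRegion, flank: int = DEFAULT_FLANK) -> dict[int, str]:
    """Zone label per region residue by distance to the nearest modified residue."""
    positions = np.arange(region.start, region.end + 1)
    site_pos = np.asarray(region.site_positions)
    dist = np.abs(positions[:, None] - site_pos[None, :]).min(axis=1)
    zones = np.where(dist == 0, ZONE_DI, np.where(dist <= 2, ZONE_N1, ZONE_N2))
    if dist.max() > flank:  # cannot happen for regions built with this flank
        raise ValueError("region contains residues beyond the flank of every site")
    return dict(zip(positions.tolist(), zones.tolist()))


def cluster_bins(region: PTMRegion, flank: int = DEFAULT_FLANK, cap: int = CLUSTER_CAP) -> dict[int, int]:
    """Per-residue count of modified residues within ±flank, capped at *cap* (5+)."""
    positions = np.arange(region.start, region.end + 1)
    site_pos = np.asarray(region.site_positions)
    counts = (np.abs(positions[:, None] - site_pos[None, :]) <= flank).sum(axis=1)
    return dict(zip(positions.tolist(), np.minimum(counts, cap).tolist()))


def filter_by_support(sites: Sequence[PTMSite], min_pubs: int) -> list[PTMSite]:
    """Keep sites observed in at least *min_pubs* independent datasets."""
    kept = [s for s in sites if s.n_pubs >= min_pubs]
    if sites and not kept:
        warnings.warn(f"min_pubs={min_pubs} removed all {len(sites)} sites", stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# tabular conversions and masks

def sites_to_frame(sites: Sequence[PTMSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [s.protein for s in sites],
            "position": [s.position for s in sites],
            "residue": [s.residue for s in sites],
            "ptm_type": [s.ptm_type for s in sites],
            "n_pubs": [s.n_pubs for s in sites],
            "enzymes": [";".join(s.enzymes) for s in sites],
        }
    )


def frame_to_sites(df: pd.DataFrame) -> list[PTMSite]:
    out = []
    for row in df.itertuples(index=False):
        enzymes = tuple(str(row.enzymes).split(";")) if getattr(row, "enzymes", "") not in ("", None) and not pd.isna(row.enzymes) else ()
        out.append(
            PTMSite(str(row.protein), int(row.position), str(row.residue), str(row.ptm_type),
                    int(getattr(row, "n_pubs", 1)), enzymes)
        )
    return out


def regions_to_frame(regions: Sequence[PTMRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_sites": [len(r.site_positions) for r in regions],
            "types": [",".join(sorted(r.types)) for r in regions],
        }
    )


def region_masks(
    regions: Sequence[PTMRegion], protein_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Boolean in-region mask per protein (index 0 = residue 1)."""
    masks = {p: np.zeros(n, dtype=bool) for p, n in protein_lengths.items()}
    for r in regions:
        masks[r.protein][r.start - 1 : r.end] = True
    return masks


def zone_maps(regions: Sequence[PTMRegion], flank: int = DEFAULT_FLANK) -> dict[str, dict[int, str]]:
    """Zone label per (protein, position) over all regions."""
    out: dict[str, dict[int, str]] = {}
    for r in regions:
        out.setdefault(r.protein, {}).update(classify_zones(r, flank))
    return out


def cluster_maps(regions: Sequence[PTMRegion], flank: int = DEFAULT_FLANK) -> dict[str, dict[int, int]]:
    out: dict[str, dict[int, int]] = {}
    for r in regions:
        out.setdefault(r.protein, {}).update(cluster_bins(r, flank))
    return out
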