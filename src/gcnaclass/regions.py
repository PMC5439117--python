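"""Genomic region definitions (GRCh37) used for copy-number calling.

A :class:`RegionMap` names the regions the caller evaluates: chromosome
arms, whole chromosomes, and focal genes.  Each region carries a genomic
interval (for the segment route) and a list of member gene symbols (for
the gene-score matrix route).  The default map covers every autosome arm
plus the focal genes CDK4, MDM2, CDKN2A and EGFR, with member genes taken
from a deterministic synthetic probe panel laid out along each arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# GRCh37 chromosome lengths and p/q boundary (approximate centromere
# midpoint).  1-based inclusive coordinates throughout.
CHROM_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}

CENTROMERES: dict[str, int] = {
    "1": 125000000, "2": 93300000, "3": 91000000, "4": 50400000,
    "5": 48400000, "6": 61000000, "7": 59900000, "8": 45600000,
    "9": 49000000, "10": 40200000, "11": 53700000, "12": 35800000,
    "13": 17900000, "14": 17600000, "15": 19000000, "16": 36600000,
    "17": 24000000, "18": 17200000, "19": 26500000, "20": 27500000,
    "21": 13200000, "22": 14700000, "X": 60600000, "Y": 12500000,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

# Focal genes of interest, GRCh37 coordinates.
FOCAL_GENES: dict[str, tuple[str, int, int]] = {
    "CDK4": ("12", 58141510, 58149796),
    "MDM2": ("12", 69201956, 69239214),
    "CDKN2A": ("9", 21967751, 21995300),
    "EGFR": ("7", 55086714, 55324313),
}


@dataclass(frozen=True)
class Region:
    name: str
    kind: str  # "arm" | "chrom" | "gene"
    chrom: str
    start: int
    end: int
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("arm", "chrom", "gene"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval for region {self.name}")
        if self.chrom in CHROM_LENGTHS and self.end > CHROM_LENGTHS[self.chrom]:
            raise ValueError(f"region {self.name} exceeds chromosome {self.chrom} bounds")


@dataclass
class RegionMap:
    """Named genomic regions with gene membership."""

    regions: dict[str, Region] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Region:
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(f"unknown region {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def names(self) -> list[str]:
        return list(self.regions)

    def add(self, region: Region) -> None:
        self.regions[region.name] = region

    def require(self, names: list[str]) -> None:
        missing = [n for n in names if n not in self.regions]
        if missing:
            raise KeyError(f"region map missing required regions: {missing}")


def arm_interval(chrom: str, arm: str) -> tuple[int, int]:
    cen = CENTROMERES[chrom]
    if arm == "p":
        return 1, cen
    if arm == "q":
        return cen + 1, CHROM_LENGTHS[chrom]
    raise ValueError(f"bad arm {arm!r}")


def synthetic_gene_panel(genes_per_arm: int = 4) -> pd.DataFrame:
    """Deterministic probe-like gene panel: evenly spaced genes on every
    autosome arm plus the real focal genes.

    Returns a frame with columns gene, chrom, start, end, arm.
    """
    rows = []
    for chrom in AUTOSOMES:
        for arm in ("p", "q"):
            lo, hi = arm_interval(chrom, arm)
            span = hi - lo + 1
            for i in range(genes_per_arm):
                # midpoint of the i-th of genes_per_arm equal slices
                s = lo + (2 * i + 1) * span // (2 * genes_per_arm)
                rows.append((f"S{chrom}{arm}_{i + 1}", chrom, s, min(s + 9999, hi), f"{chrom}{arm}"))
    for g, (chrom, s, e) in FOCAL_GENES.items():
        arm = "p" if s <= CENTROMERES[chrom] else "q"
        rows.append((g, chrom, s, e, f"{chrom}{arm}"))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "arm"])


def default_region_map(panel: pd.DataFrame | None = None) -> RegionMap:
    """Region map over all autosome arms and chromosomes plus focal genes.

    Gene membership is assigned from ``panel`` (default: the synthetic
    panel) by genomic position.
    """
    if panel is None:
        panel = synthetic_gene_panel()
    rmap = RegionMap()
    for chrom in AUTOSOMES:
        chrom_genes: list[str] = []
        for arm in ("p", "q"):
            lo, hi = arm_interval(chrom, arm)
            members = panel.loc[
                (panel["chrom"] == chrom) & (panel["start"] >= lo) & (panel["start"] <= hi),
                "gene",
            ].tolist()
            rmap.add(Region(f"{chrom}{arm}", "arm", chrom, lo, hi, tuple(members)))
            chrom_genes.extend(members)
        rmap.add(Region(f"chr{chrom}", "chrom", chrom, 1, CHROM_LENGTHS[chrom], tuple(chrom_genes)))
    for g, (chrom, s, e) in FOCAL_GENES.items():
        rmap.add(Region(g, "gene", chrom, s, e, (g,)))
    return rmap


def read_region_map(path: str) -> RegionMap:
    """Read a region map from TSV with columns name, kind, chrom, start, end, genes.

    ``genes`` is a comma-separated member list and may be empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["name", "kind", "chrom", "start", "end"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"region file missing columns {missing}; expected header {expected + ['genes']}")
    rmap = RegionMap()
    for _, row in df.iterrows():
        genes: tuple[str, ...] = ()
        if "genes" in df.columns and isinstance(row.get("genes"), str) and row["genes"]:
            genes = tuple(g.strip() for g in row["genes"].split(",") if g.strip())
        rmap.add(Region(row["name"], row["kind"], str(row["chrom"]).removeprefix("chr"),
                        int(row["start"]), int(row["end"]), genes))
    return rmap


def write_region_map(rmap: RegionMap, path: str) -> None:
    rows = [
        (r.name, r.kind, r.chrom, r.start, r.end, ",".join(r.genes))
        for r in rmap.regions.values()
    ]
    pd.DataFrame(rows, columns=["name", "kind", "chrom", "start", "end", "genes"]).to_csv(
        path, sep="\t", index=False
    )
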