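"""Discrete copy-number event calling from continuous evidence.

Two evidence routes are supported:

* gene-score matrices (GISTIC2.0-style), thresholded at ±0.5 for broad
  gains/losses, and
* per-sample segment tables (log2 ratios), baseline-corrected per sample
  and thresholded at ±0.1 for broad events.

Focal gene amplifications / homozygous deletions use ±0.6 on either
route.  Boundary values call as events (inclusive comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GisticMatrix
from .regions import AUTOSOMES, Region, RegionMap

GAIN, LOSS, NEUTRAL, MISSING = "gain", "loss", "neutral", "missing"
AMPLIFIED, HOMODEL = "amplified", "homozygously_deleted"

#: boolean flags every call set derives, in output order
FLAG_NAMES = (
    "codel_1p19q", "chr1_gain", "chr7_gain", "chr14_gain", "chr19_gain",
    "chr10_loss", "loss_9p", "cdk4_amp", "mdm2_amp", "cdk4_mdm2_coamp",
    "cdkn2a_homodel",
)

#: regions a call set needs to derive all flags
REQUIRED_REGIONS = (
    "1p", "19q", "9p", "chr1", "chr7", "chr10", "chr14", "chr19",
    "CDK4", "MDM2", "CDKN2A",
)

FOCAL_GENE_REGIONS = ("CDK4", "MDM2", "CDKN2A", "EGFR")


@dataclass(frozen=True)
class Thresholds:
    """Log2-scale calling thresholds (all unitless)."""

    gistic_gain: float = 0.5
    gistic_loss: float = -0.5
    seg_gain: float = 0.1
    seg_loss: float = -0.1
    amp: float = 0.6
    homodel: float = -0.6

    def __post_init__(self) -> None:
        if not (self.gistic_gain > 0 > self.gistic_loss):
            raise ValueError("gain threshold must be > 0 > loss threshold")
        if not (self.seg_gain > 0 > self.seg_loss):
            raise ValueError("segment gain threshold must be > 0 > loss threshold")
        if not (self.amp > self.gistic_gain):
            raise ValueError("focal amp threshold must exceed broad gain threshold")
        if not (self.homodel < self.gistic_loss):
            raise ValueError("focal deletion threshold must be below broad loss threshold")


@dataclass
class CnaCallSet:
    """Discrete copy-number states and derived flags for one sample."""

    sample_id: str
    region_states: dict[str, str] = field(default_factory=dict)
    gene_states: dict[str, str] = field(default_factory=dict)
    flags: dict[str, bool | None] = field(default_factory=dict)
    alteration_burden: int = 0


def call_state(value: float, gain_thr: float, loss_thr: float) -> str:
    """Ternary broad call: gain if value ≥ gain_thr, loss if ≤ loss_thr."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    if not math.isfinite(value):
        raise ValueError(f"non-finite copy-number value {value!r}")
    if value >= gain_thr:
        return GAIN
    if value <= loss_thr:
        return LOSS
    return NEUTRAL


def call_gene_focal(value: float, amp_thr: float = 0.6, del_thr: float = -0.6) -> str:
    """Focal gene call at the amplification / homozygous-deletion thresholds."""
    state = call_state(value, amp_thr, del_thr)
    return {GAIN: AMPLIFIED, LOSS: HOMODEL}.get(state, state)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median; an exact half-mass split returns the midpoint of
    the adjacent values.  Translation-equivariant (median(v+c) = median(v)+c).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        return float("nan")
    if np.any(weights < 0):
        raise ValueError("negative weight")
    total = weights.sum()
    if total <= 0:
        return float("nan")
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = total / 2.0
    k = int(np.searchsorted(cum, half, side="left"))
    if cum[k] == half and k + 1 < len(v):
        return float((v[k] + v[k + 1]) / 2.0)
    return float(v[k])


def baseline_correct(seg: pd.DataFrame) -> pd.DataFrame:
    """Per-sample baseline correction of a segment table.

    Shifts each sample's log2 values so its length-weighted median over
    autosomal segments is exactly 0.  Idempotent.
    """
    out = seg.copy()
    for sample_id, idx in seg.groupby("sample_id").groups.items():
        sub = seg.loc[idx]
        auto = sub[sub["chrom"].isin(AUTOSOMES)]
        if auto.empty:
            raise ValueError(f"sample {sample_id!r} has no autosomal segments")
        lengths = (auto["end"] - auto["start"] + 1).to_numpy(dtype=float)
        shift = weighted_median(auto["log2"].to_numpy(), lengths)
        out.loc[idx, "log2"] = seg.loc[idx, "log2"] - shift
    return out


def region_median(seg: pd.DataFrame, region: Region) -> pd.Series:
    """Per-sample length-weighted median log2 over a genomic region.

    Segments are intersected with the region interval and weighted by the
    overlap length.  Samples with zero overlap get NaN.
    """
    sub = seg[seg["chrom"] == region.chrom]
    result: dict[str, float] = {}
    for sample_id in pd.unique(seg["sample_id"]):
        s = sub[sub["sample_id"] == sample_id]
        if s.empty:
            result[sample_id] = float("nan")
            continue
        lo = np.maximum(s["start"].to_numpy(), region.start)
        hi = np.minimum(s["end"].to_numpy(), region.end)
        overlap = (hi - lo + 1).astype(float)
        mask = overlap > 0
        if not mask.any():
            result[sample_id] = float("nan")
            continue
        result[sample_id] = weighted_median(s["log2"].to_numpy()[mask], overlap[mask])
    return pd.Series(result, name=region.name)


def _gistic_region_value(scores: pd.Series, region: Region) -> float:
    members = [g for g in region.genes if g in scores.index]
    if not members:
        return float("nan")
    return float(np.median(scores.loc[members].to_numpy()))


def _derive_flags(region_states: dict[str, str], gene_states: dict[str, str]) -> dict[str, bool | None]:
    def rs(name: str, want: str) -> bool | None:
        st = region_states.get(name, MISSING)
        return None if st == MISSING else st == want

    def gs(name: str, want: str) -> bool | None:
        st = gene_states.get(name, MISSING)
        return None if st == MISSING else st == want

    def both(a: bool | None, b: bool | None) -> bool | None:
        if a is None or b is None:
            return None
        return a and b

    flags: dict[str, bool | None] = {
        "codel_1p19q": both(rs("1p", LOSS), rs("19q", LOSS)),
        "chr1_gain": rs("chr1", GAIN),
        "chr7_gain": rs("chr7", GAIN),
        "chr14_gain": rs("chr14", GAIN),
        "chr19_gain": rs("chr19", GAIN),
        "chr10_loss": rs("chr10", LOSS),
        "loss_9p": rs("9p", LOSS),
        "cdk4_amp": gs("CDK4", AMPLIFIED),
        "mdm2_amp": gs("MDM2", AMPLIFIED),
        "cdkn2a_homodel": gs("CDKN2A", HOMODEL),
    }
    flags["cdk4_mdm2_coamp"] = both(flags["cdk4_amp"], flags["mdm2_amp"])
    return flags


def make_callset(
    sample_id: str,
    *,
    gistic: GisticMatrix | None = None,
    segments: pd.DataFrame | None = None,
    regions: RegionMap,
    thresholds: Thresholds = Thresholds(),
    mutated_genes: set[str] | None = None,
    _region_medians: pd.DataFrame | None = None,
) -> CnaCallSet:
    """Build the discrete call set for one sample.

    Exactly one of ``gistic`` / ``segments`` supplies the evidence; the
    broad threshold regime follows the source (±0.5 gene scores, ±0.1
    baseline-corrected segment medians).  ``segments`` must already be
    baseline-corrected.
    """
    if (gistic is None) == (segments is None):
        raise ValueError("provide exactly one of gistic or segments")
    regions.require(list(REQUIRED_REGIONS))

    if gistic is not None:
        gain_thr, loss_thr = thresholds.gistic_gain, thresholds.gistic_loss
        if _region_medians is not None:
            value_of = lambda r: float(_region_medians.at[sample_id, r.name])  # noqa: E731
        else:
            scores = gistic.sample_scores(sample_id)
            value_of = lambda r: _gistic_region_value(scores, r)  # noqa: E731
    else:
        gain_thr, loss_thr = thresholds.seg_gain, thresholds.seg_loss
        if _region_medians is not None:
            value_of = lambda r: float(_region_medians.at[sample_id, r.name])  # noqa: E731
        else:
            sub = segments[segments["sample_id"] == sample_id]
            value_of = lambda r: float(region_median(sub, r).get(sample_id, float("nan")))  # noqa: E731

    region_states: dict[str, str] = {}
    gene_states: dict[str, str] = {}
    for name, region in regions.regions.items():
        if region.kind == "gene":
            gene_states[name] = call_gene_focal(value_of(region), thresholds.amp, thresholds.homodel)
        else:
            region_states[name] = call_state(value_of(region), gain_thr, loss_thr)

    flags = _derive_flags(region_states, gene_states)
    burden = sum(1 for s in region_states.values() if s in (GAIN, LOSS))
    burden += sum(1 for s in gene_states.values() if s in (AMPLIFIED, HOMODEL))
    if mutated_genes:
        burden += len(mutated_genes)
    return CnaCallSet(sample_id, region_states, gene_states, flags, burden)


def make_callsets(
    *,
    gistic: GisticMatrix | None = None,
    segments: pd.DataFrame | None = None,
    regions: RegionMap,
    thresholds: Thresholds = Thresholds(),
    mutations: pd.DataFrame | None = None,
    correct_baseline: bool = True,
) -> list[CnaCallSet]:
    """Call every sample in the input; see :func:`make_callset`."""
    if (gistic is None) == (segments is None):
        raise ValueError("provide exactly one of gistic or segments")
    mut_by_sample: dict[str, set[str]] = {}
    if mutations is not None:
        mut_by_sample = mutations.groupby("sample_id")["gene"].agg(set).to_dict()
    if gistic is not None:
        # vectorized per-region medians over member genes, all samples at once
        gene_idx = {g: i for i, g in enumerate(gistic.genes)}
        med_cols = {}
        for name, region in regions.regions.items():
            members = [gene_idx[g] for g in region.genes if g in gene_idx]
            if members:
                med_cols[name] = np.median(gistic.scores[members, :], axis=0)
            else:
                med_cols[name] = np.full(len(gistic.samples), np.nan)
        medians = pd.DataFrame(med_cols, index=gistic.samples)
        return [
            make_callset(
                s, gistic=gistic, regions=regions, thresholds=thresholds,
                mutated_genes=mut_by_sample.get(s), _region_medians=medians,
            )
            for s in gistic.samples
        ]
    if correct_baseline:
        segments = baseline_correct(segments)
    # precompute per-region medians once (vectorized over samples)
    medians = pd.DataFrame(
        {name: region_median(segments, region) for name, region in regions.regions.items()}
    )
    return [
        make_callset(
            s, segments=segments, regions=regions, thresholds=thresholds,
            mutated_genes=mut_by_sample.get(s), _region_medians=medians,
        )
        for s in pd.unique(segments["sample_id"])
    ]


def callsets_frame(callsets: list[CnaCallSet]) -> pd.DataFrame:
    """Flatten call sets to a per-sample table of flags and burden."""
    rows = []
    for cs in callsets:
        row: dict[str, object] = {"sample_id": cs.sample_id}
        for f in FLAG_NAMES:
            row[f] = cs.flags.get(f)
        row["alteration_burden"] = cs.alteration_burden
        rows.append(row)
    return pd.DataFrame(rows)


def _region_sort_key(region: Region) -> tuple:
    chrom_order = {c: i for i, c in enumerate(list(AUTOSOMES) + ["X", "Y"])}
    kind_order = {"chrom": 0, "arm": 1, "gene": 2}
    return (chrom_order.get(region.chrom, 99), kind_order[region.kind], region.start, region.name)


def cna_frequency(
    callsets: list[CnaCallSet],
    clusters: pd.Series | dict[str, str],
    regions: RegionMap,
    region_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster gain/loss/neutral frequencies for each region.

    Output rows are ordered chromosome 1→22 within each cluster; counts
    are exact so gain + loss + neutral frequencies sum to 1.
    """
    clusters = dict(clusters) if not isinstance(clusters, dict) else clusters
    if region_names is None:
        region_names = regions.names()
    ordered = sorted(
        (regions[n] for n in region_names if regions[n].kind != "gene"),
        key=_region_sort_key,
    )
    by_cluster: dict[str, list[CnaCallSet]] = {}
    for cs in callsets:
        cl = clusters.get(cs.sample_id)
        if cl is not None:
            by_cluster.setdefault(cl, []).append(cs)
    for cl, members in by_cluster.items():
        if not members:
            raise ValueError(f"cluster {cl!r} has no samples")
    if not by_cluster:
        raise ValueError("no samples with cluster labels")
    rows = []
    for cl in sorted(by_cluster):
        members = by_cluster[cl]
        for region in ordered:
            states = [cs.region_states.get(region.name, MISSING) for cs in members]
            known = [s for s in states if s != MISSING]
            n = len(known)
            if n == 0:
                continue
            n_gain = sum(1 for s in known if s == GAIN)
            n_loss = sum(1 for s in known if s == LOSS)
            rows.append(
                {
                    "cluster": cl, "region": region.name, "n": n,
                    "gain_freq": n_gain / n, "loss_freq": n_loss / n,
                    "neutral_freq": (n - n_gain - n_loss) / n,
                }
            )
    return pd.DataFrame(rows)
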