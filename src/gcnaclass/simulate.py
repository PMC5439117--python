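"""Synthetic glioma cohort generator.

Emits the four pipeline input tables (gene-score matrix, segment table,
mutation table, clinical table) plus a per-sample ground-truth table, so
every downstream stage can be exercised and verified without external
data.

Construction per sample: a cluster is drawn from the configured sizes;
marker flags are Bernoulli at the configured per-cluster prevalences
with structural constraints enforced (1p/19q codeletion restricted to
the oligodendroglial cluster, IDH1/IDH2 mutually exclusive, IDH mutation
absent from the wildtype cluster); the prognostic subtype follows from
the marker flags via the same rule tables the classifier uses; overall
survival is exponential at the subtype's configured median with
independent uniform censoring; age comes from the cluster's normal
mixture.  Copy-number evidence encodes each event as gain +1.0 / loss
−1.0 / amplification +2.0 / homozygous deletion −2.0 plus Gaussian
noise.

Identifiability constraint: when an arm-level 9p loss is drawn without a
CDKN2A homozygous deletion, the CDKN2A interval is carved out at 0 so
the focal-deletion call (threshold −0.6) cannot fire from the broad
event alone; with noise_sd=0 the caller then recovers every generated
flag exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GisticMatrix
from .regions import CENTROMERES, CHROM_LENGTHS, FOCAL_GENES, AUTOSOMES, arm_interval, synthetic_gene_panel
from .subtypes import RuleTables, SubtypeLabel
from .clusters import ClusterLabel

OLIGO = ClusterLabel.OLIGO_IDHmut_CODEL.value
MUT = ClusterLabel.ASTRO_IDHmut.value
WT = ClusterLabel.ASTRO_IDHwt.value

#: markers the generator understands. "idh1" is the probability that an
#: IDH mutation (always present outside the wildtype cluster) hits IDH1
#: rather than IDH2; the rest are per-cluster event prevalences.
KNOWN_MARKERS = (
    "idh1", "tp53", "atrx", "braf", "codel_1p19q",
    "chr1_gain", "chr7_gain", "chr14_gain", "chr19_gain",
    "chr10_loss", "loss_9p",
    "cdk4_amp", "mdm2_amp", "cdk4_mdm2_coamp", "cdkn2a_homodel",
)

MARKER_FLAG_COLUMNS = (
    "idh1_mut", "idh2_mut", "tp53_mut", "atrx_mut", "braf_mut",
    "codel_1p19q", "chr1_gain", "chr7_gain", "chr14_gain", "chr19_gain",
    "chr10_loss", "loss_9p", "cdk4_amp", "mdm2_amp", "cdk4_mdm2_coamp",
    "cdkn2a_homodel",
)


def _default_prevalence() -> dict[str, dict[str, float]]:
    return {
        OLIGO: {
            "idh1": 0.7, "tp53": 0.1, "atrx": 0.05, "braf": 0.0,
            "codel_1p19q": 1.0, "chr1_gain": 0.0, "chr7_gain": 0.1,
            "chr14_gain": 0.0, "chr19_gain": 0.0, "chr10_loss": 0.1,
            "loss_9p": 0.1, "cdk4_amp": 0.0, "mdm2_amp": 0.0,
            "cdk4_mdm2_coamp": 0.0, "cdkn2a_homodel": 0.02,
        },
        MUT: {
            "idh1": 0.95, "tp53": 0.85, "atrx": 0.7, "braf": 0.0,
            "codel_1p19q": 0.0, "chr1_gain": 0.05, "chr7_gain": 0.25,
            "chr14_gain": 0.15, "chr19_gain": 0.05, "chr10_loss": 0.1,
            "loss_9p": 0.3, "cdk4_amp": 0.08, "mdm2_amp": 0.05,
            "cdk4_mdm2_coamp": 0.02, "cdkn2a_homodel": 0.1,
        },
        WT: {
            "idh1": 0.0, "tp53": 0.3, "atrx": 0.05, "braf": 0.03,
            "codel_1p19q": 0.0, "chr1_gain": 0.25, "chr7_gain": 0.8,
            "chr14_gain": 0.05, "chr19_gain": 0.25, "chr10_loss": 0.75,
            "loss_9p": 0.45, "cdk4_amp": 0.1, "mdm2_amp": 0.07,
            "cdk4_mdm2_coamp": 0.08, "cdkn2a_homodel": 0.4,
        },
    }


def _default_medians() -> dict[str, float]:
    # W1–W3 / M1–M3 medians follow the reported values; W4 and the
    # codeleted cluster have no printed median — placeholders, config-exposed.
    return {
        "W1": 6.6, "W2": 12.7, "W3": 15.2, "W4": 18.0,
        "M1": 23.3, "M2": 63.0, "M3": 94.5,
        "OLIGO_NA": 150.0,
    }


def _default_age_params() -> dict[str, list[tuple[float, float, float]]]:
    # (mean, sd, weight) mixture components per cluster
    return {
        WT: [(59.5, 8.0, 1.0)],
        MUT: [(29.0, 7.0, 1.0)],
        OLIGO: [(38.0, 5.0, 0.5), (56.0, 5.0, 0.5)],
    }


def _default_grades() -> dict[str, dict[str, float]]:
    return {
        OLIGO: {"II": 0.5, "III": 0.5, "IV": 0.0},
        MUT: {"II": 0.35, "III": 0.35, "IV": 0.3},
        WT: {"II": 0.08, "III": 0.12, "IV": 0.8},
    }


@dataclass
class GeneratorConfig:
    n_per_cluster: dict[str, int] = field(
        default_factory=lambda: {OLIGO: 176, MUT: 251, WT: 351}
    )
    marker_prevalence: dict[str, dict[str, float]] = field(default_factory=_default_prevalence)
    subtype_median_os: dict[str, float] = field(default_factory=_default_medians)
    censoring_rate: float = 0.2
    age_params: dict[str, list[tuple[float, float, float]]] = field(default_factory=_default_age_params)
    grade_distribution: dict[str, dict[str, float]] = field(default_factory=_default_grades)
    #: optional override: grade distribution keyed by subtype label (falls
    #: back to the cluster distribution when a subtype is absent)
    grade_distribution_by_subtype: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for cl, prev in self.marker_prevalence.items():
            for marker, p in prev.items():
                if marker not in KNOWN_MARKERS:
                    raise ValueError(f"unknown marker {marker!r} in config for cluster {cl!r}")
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prevalence out of [0,1] for ({cl}, {marker}): {p}")
        for cl, n in self.n_per_cluster.items():
            if n < 0:
                raise ValueError(f"negative cluster size for {cl!r}")
        for st, m in self.subtype_median_os.items():
            if m <= 0:
                raise ValueError(f"non-positive median OS for subtype {st!r}")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ValueError("censoring_rate must be in [0,1]")
        for cl, comps in self.age_params.items():
            w = sum(c[2] for c in comps)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"age mixture weights for {cl!r} must sum to 1 (got {w})")
        for dist_map in (self.grade_distribution, self.grade_distribution_by_subtype):
            for key, dist in dist_map.items():
                s = sum(dist.values())
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(f"grade distribution for {key!r} must sum to 1 (got {s})")

    def with_overrides(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorConfig":
        kwargs = {}
        for f_ in (
            "n_per_cluster", "marker_prevalence", "subtype_median_os", "censoring_rate",
            "grade_distribution", "grade_distribution_by_subtype", "noise_sd", "seed",
        ):
            if f_ in doc:
                kwargs[f_] = doc[f_]
        if "age_params" in doc:
            kwargs["age_params"] = {
                cl: [tuple(c) for c in comps] for cl, comps in doc["age_params"].items()
            }
        return cls(**kwargs)


@dataclass
class SyntheticCohort:
    gistic: GisticMatrix
    segments: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame

    def sample_ids(self) -> list[str]:
        return list(self.clinical["sample_id"])


def _draw_flags(cluster: str, prev: dict[str, float], rng: np.random.Generator) -> dict[str, bool]:
    p = dict(prev)
    flags: dict[str, bool] = {}
    # IDH: structural — mutant clusters always carry exactly one IDH mutation
    if cluster == WT:
        flags["idh1_mut"] = flags["idh2_mut"] = False
    else:
        is_idh1 = rng.random() < p.get("idh1", 0.9)
        flags["idh1_mut"], flags["idh2_mut"] = is_idh1, not is_idh1
    for gene in ("tp53", "atrx", "braf"):
        flags[f"{gene}_mut"] = bool(rng.random() < p.get(gene, 0.0))
    # codeletion only in the oligodendroglial cluster
    codel = cluster == OLIGO and rng.random() < p.get("codel_1p19q", 0.0)
    flags["codel_1p19q"] = codel
    for marker in ("chr1_gain", "chr7_gain", "chr14_gain", "chr19_gain", "chr10_loss", "loss_9p"):
        flags[marker] = bool(rng.random() < p.get(marker, 0.0))
    if codel:
        # a codeleted genome cannot simultaneously carry whole-chr1/19 gains
        flags["chr1_gain"] = False
        flags["chr19_gain"] = False
    coamp = rng.random() < p.get("cdk4_mdm2_coamp", 0.0)
    if coamp:
        flags["cdk4_amp"] = flags["mdm2_amp"] = True
    else:
        flags["cdk4_amp"] = bool(rng.random() < p.get("cdk4_amp", 0.0))
        flags["mdm2_amp"] = bool(rng.random() < p.get("mdm2_amp", 0.0))
        if flags["cdk4_amp"] and flags["mdm2_amp"]:
            flags["mdm2_amp"] = False  # solo prevalences stay solo
    flags["cdk4_mdm2_coamp"] = flags["cdk4_amp"] and flags["mdm2_amp"]
    flags["cdkn2a_homodel"] = bool(rng.random() < p.get("cdkn2a_homodel", 0.0))
    return flags


def _subtype_from_flags(cluster: str, flags: dict[str, bool], tables: RuleTables) -> str:
    if cluster == OLIGO:
        return SubtypeLabel.OLIGO_NA.value
    table = tables.mutant if cluster == MUT else tables.wildtype
    return table.classify({k: flags[k] for k in flags}).value


def _panel_masks(panel: pd.DataFrame) -> dict[str, np.ndarray]:
    chrom = panel["chrom"].to_numpy()
    arm = panel["arm"].to_numpy()
    gene = panel["gene"].to_numpy()
    focal = np.isin(gene, ("CDK4", "MDM2", "CDKN2A"))
    return {
        "chr1": (chrom == "1") & ~focal,
        "chr7": (chrom == "7") & ~focal,
        "chr14": (chrom == "14") & ~focal,
        "chr19": (chrom == "19") & ~focal,
        "chr10": (chrom == "10") & ~focal,
        "9p": (arm == "9p") & ~focal,
        "1p": (arm == "1p") & ~focal,
        "19q": (arm == "19q") & ~focal,
        "CDK4": gene == "CDK4",
        "MDM2": gene == "MDM2",
        "CDKN2A": gene == "CDKN2A",
    }


def _gene_signal_vector(masks: dict[str, np.ndarray], flags: dict[str, bool]) -> np.ndarray:
    n = masks["CDK4"].size
    sig = np.zeros(n)
    if flags["chr1_gain"]:
        sig[masks["chr1"]] = 1.0
    if flags["chr7_gain"]:
        sig[masks["chr7"]] = 1.0
    if flags["chr14_gain"]:
        sig[masks["chr14"]] = 1.0
    if flags["chr19_gain"]:
        sig[masks["chr19"]] = 1.0
    if flags["chr10_loss"]:
        sig[masks["chr10"]] = -1.0
    if flags["loss_9p"]:
        sig[masks["9p"]] = -1.0
    if flags["codel_1p19q"]:
        sig[masks["1p"]] = -1.0
        sig[masks["19q"]] = -1.0
    # focal genes override broad events (CDKN2A carved out of 9p loss)
    if flags["cdk4_amp"]:
        sig[masks["CDK4"]] = 2.0
    if flags["mdm2_amp"]:
        sig[masks["MDM2"]] = 2.0
    if flags["cdkn2a_homodel"]:
        sig[masks["CDKN2A"]] = -2.0
    return sig


def _arm_base_value(chrom: str, arm_letter: str, flags: dict[str, bool]) -> float:
    value = 0.0
    if chrom == "1" and flags["chr1_gain"]:
        value = 1.0
    if chrom == "7" and flags["chr7_gain"]:
        value = 1.0
    if chrom == "14" and flags["chr14_gain"]:
        value = 1.0
    if chrom == "19" and flags["chr19_gain"]:
        value = 1.0
    if chrom == "10" and flags["chr10_loss"]:
        value = -1.0
    if chrom == "9" and arm_letter == "p" and flags["loss_9p"]:
        value = -1.0
    if flags["codel_1p19q"]:
        if (chrom, arm_letter) in (("1", "p"), ("19", "q")):
            value = -1.0
    return value


def _sample_segments(sample_id: str, flags: dict[str, bool], noise_sd: float,
                     rng: np.random.Generator) -> list[tuple]:
    """Non-overlapping segments tiling every autosome, with focal gene
    intervals carved out where their value differs from the arm base."""
    focal_values = {
        "CDK4": 2.0 if flags["cdk4_amp"] else None,
        "MDM2": 2.0 if flags["mdm2_amp"] else None,
        "CDKN2A": -2.0 if flags["cdkn2a_homodel"] else (0.0 if flags["loss_9p"] else None),
    }
    rows = []
    for chrom in AUTOSOMES:
        for arm_letter in ("p", "q"):
            lo, hi = arm_interval(chrom, arm_letter)
            base = _arm_base_value(chrom, arm_letter, flags)
            carves = []
            for gene, val in focal_values.items():
                if val is None:
                    continue
                gchrom, gs, ge = FOCAL_GENES[gene]
                if gchrom == chrom and lo <= gs <= hi:
                    carves.append((gs, ge, val))
            carves.sort()
            cur = lo
            for gs, ge, val in carves:
                if gs > cur:
                    rows.append((sample_id, chrom, cur, gs - 1, base + rng.normal(0, noise_sd) if noise_sd else base))
                rows.append((sample_id, chrom, gs, ge, val + rng.normal(0, noise_sd) if noise_sd else val))
                cur = ge + 1
            if cur <= hi:
                rows.append((sample_id, chrom, cur, hi, base + rng.normal(0, noise_sd) if noise_sd else base))
    return rows


def _draw_age(cluster: str, comps: list[tuple[float, float, float]], rng: np.random.Generator) -> float:
    weights = np.array([c[2] for c in comps])
    idx = rng.choice(len(comps), p=weights / weights.sum())
    mean, sd, _ = comps[idx]
    return float(np.clip(rng.normal(mean, sd), 1.0, 100.0))


def _draw_grade(cluster: str, subtype: str, config: GeneratorConfig, rng: np.random.Generator) -> str:
    dist = config.grade_distribution_by_subtype.get(subtype) or config.grade_distribution[cluster]
    grades = ["II", "III", "IV"]
    probs = np.array([dist.get(g, 0.0) for g in grades])
    return grades[rng.choice(3, p=probs / probs.sum())]


def _draw_histology(cluster: str, grade: str, rng: np.random.Generator) -> str:
    if cluster == OLIGO:
        if grade == "II":
            return "O" if rng.random() < 0.8 else "OA"
        return "AO" if rng.random() < 0.8 else "AOA"
    if grade == "IV":
        return "GBM"
    if grade == "II":
        return "A" if rng.random() < 0.7 else "OA"
    return "AA" if rng.random() < 0.7 else "AOA"


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort; identical config + seed ⇒ identical cohort."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tables = RuleTables()
    panel = synthetic_gene_panel()
    max_median = max(config.subtype_median_os.values())

    clusters_order = [OLIGO, MUT, WT]
    sample_rows = []
    idx = 0
    for cluster in clusters_order:
        n = config.n_per_cluster.get(cluster, 0)
        prev = config.marker_prevalence.get(cluster, {})
        for _ in range(n):
            idx += 1
            sid = f"SYN-{idx:04d}"
            flags = _draw_flags(cluster, prev, rng)
            subtype = _subtype_from_flags(cluster, flags, tables)
            median = config.subtype_median_os[subtype]
            os_true = rng.exponential(median / np.log(2.0))
            event = 1
            os_obs = os_true
            if config.censoring_rate > 0 and rng.random() < config.censoring_rate:
                c = rng.uniform(0.0, 2.0 * max_median)
                if c < os_true:
                    os_obs, event = c, 0
            age = _draw_age(cluster, config.age_params[cluster], rng)
            grade = _draw_grade(cluster, subtype, config, rng)
            histology = _draw_histology(cluster, grade, rng)
            kps = float(np.clip(round(rng.normal(85, 10) / 10) * 10, 40, 100))
            sample_rows.append(
                {
                    "sample_id": sid, "cluster": cluster, "subtype": subtype,
                    "flags": flags, "age_years": round(age, 1), "who_grade": grade,
                    "histology_2007": histology, "kps": kps,
                    "os_months": round(float(os_obs), 2), "event": event,
                }
            )

    sample_ids = [r["sample_id"] for r in sample_rows]

    # gene-score matrix: signal + noise, genes × samples
    n_genes = len(panel)
    masks = _panel_masks(panel)
    if sample_rows:
        scores = np.column_stack([_gene_signal_vector(masks, r["flags"]) for r in sample_rows])
    else:
        scores = np.zeros((n_genes, 0))
    if config.noise_sd > 0:
        scores += rng.normal(0.0, config.noise_sd, size=scores.shape)
    gistic = GisticMatrix(genes=list(panel["gene"]), samples=sample_ids, scores=scores)

    seg_rows = []
    for r in sample_rows:
        seg_rows.extend(_sample_segments(r["sample_id"], r["flags"], config.noise_sd, rng))
    segments = pd.DataFrame(seg_rows, columns=["sample_id", "chrom", "start", "end", "log2"])
    segments["log2"] = segments["log2"].astype(float)

    mut_rows = []
    gene_of = {"idh1_mut": "IDH1", "idh2_mut": "IDH2", "tp53_mut": "TP53",
               "atrx_mut": "ATRX", "braf_mut": "BRAF"}
    for r in sample_rows:
        for flag, gene in gene_of.items():
            if r["flags"][flag]:
                mut_rows.append((r["sample_id"], gene, "Missense_Mutation"))
    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "variant_class"])

    clinical = pd.DataFrame(
        [
            {
                "sample_id": r["sample_id"], "age_years": r["age_years"],
                "histology_2007": r["histology_2007"], "who_grade": r["who_grade"],
                "kps": r["kps"], "os_months": r["os_months"], "event": r["event"],
            }
            for r in sample_rows
        ]
    )

    truth_rows = []
    for r in sample_rows:
        row = {"sample_id": r["sample_id"], "cluster": r["cluster"], "subtype": r["subtype"]}
        for col in MARKER_FLAG_COLUMNS:
            row[col] = int(r["flags"][col])
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "cluster", "subtype", *MARKER_FLAG_COLUMNS])

    return SyntheticCohort(gistic=gistic, segments=segments, mutations=mutations,
                           clinical=clinical, truth=truth)


def ground_truth_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-sample truth table (the oracle for recovery tests)."""
    return cohort.truth.copy()
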