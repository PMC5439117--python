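"""Molecular cluster assignment and integrated diagnostic labels.

Each tumor maps to one of three clusters from two molecular axes: IDH1/2
mutation status and 1p/19q codeletion.  The integrated label combines
the cluster with the WHO grade into the canonical diagnostic string.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cna import CnaCallSet


class ClusterLabel(str, Enum):
    OLIGO_IDHmut_CODEL = "OLIGO_IDHmut_CODEL"
    ASTRO_IDHmut = "ASTRO_IDHmut"
    ASTRO_IDHwt = "ASTRO_IDHwt"


@dataclass
class IntegratedDiagnosis:
    cluster: ClusterLabel
    grade: str
    label: str
    warnings: list[str]


def assign_cluster(
    idh1_mut: bool, idh2_mut: bool, codel_1p19q: bool
) -> tuple[ClusterLabel, str | None]:
    """Three-way cluster rule.  Returns (label, discordance note or None).

    IDH-wildtype with codeletion is discordant (the codeleted cluster is
    IDH-mutant by definition): assigned ASTRO_IDHwt with a warning, not
    silently reclassified.
    """
    for name, v in (("idh1_mut", idh1_mut), ("idh2_mut", idh2_mut), ("codel_1p19q", codel_1p19q)):
        if v is None:
            raise ValueError(f"cannot assign cluster: flag {name} unresolved")
    idh_mut = idh1_mut or idh2_mut
    if idh_mut and codel_1p19q:
        return ClusterLabel.OLIGO_IDHmut_CODEL, None
    if idh_mut:
        return ClusterLabel.ASTRO_IDHmut, None
    note = "1p/19q codeletion with IDH-wildtype status (discordant)" if codel_1p19q else None
    return ClusterLabel.ASTRO_IDHwt, note


def assign_clusters(
    mutations: pd.DataFrame, callsets: list[CnaCallSet]
) -> pd.DataFrame:
    """Per-sample cluster table: sample_id, cluster, discordant, note."""
    mut_by_sample = mutations.groupby("sample_id")["gene"].agg(set).to_dict()
    rows = []
    for cs in callsets:
        muts = mut_by_sample.get(cs.sample_id, set())
        codel = cs.flags.get("codel_1p19q")
        label, note = assign_cluster("IDH1" in muts, "IDH2" in muts, codel)
        rows.append(
            {
                "sample_id": cs.sample_id,
                "cluster": label.value,
                "discordant": note is not None,
                "note": note or "",
            }
        )
    return pd.DataFrame(rows)


_ENTITY = {
    (ClusterLabel.OLIGO_IDHmut_CODEL, "II"): "Oligodendroglioma, IDH-mutant and 1p/19q-codeleted",
    (ClusterLabel.OLIGO_IDHmut_CODEL, "III"): "Anaplastic oligodendroglioma, IDH-mutant and 1p/19q-codeleted",
    (ClusterLabel.OLIGO_IDHmut_CODEL, "IV"): "Oligodendroglial tumor, IDH-mutant and 1p/19q-codeleted",
    (ClusterLabel.ASTRO_IDHmut, "II"): "Diffuse astrocytoma, IDH-mutant",
    (ClusterLabel.ASTRO_IDHmut, "III"): "Anaplastic astrocytoma, IDH-mutant",
    (ClusterLabel.ASTRO_IDHmut, "IV"): "Glioblastoma, IDH-mutant",
    (ClusterLabel.ASTRO_IDHwt, "II"): "Diffuse astrocytoma, IDH-wildtype",
    (ClusterLabel.ASTRO_IDHwt, "III"): "Anaplastic astrocytoma, IDH-wildtype",
    (ClusterLabel.ASTRO_IDHwt, "IV"): "Glioblastoma, IDH-wildtype",
}

_BASE_ENTITY = {
    ClusterLabel.OLIGO_IDHmut_CODEL: "Oligodendroglial tumor, IDH-mutant and 1p/19q-codeleted",
    ClusterLabel.ASTRO_IDHmut: "Astrocytic glioma, IDH-mutant",
    ClusterLabel.ASTRO_IDHwt: "Astrocytic glioma, IDH-wildtype",
}


def integrated_label(
    cluster: ClusterLabel, grade: str, histology_2007: str = "unknown"
) -> IntegratedDiagnosis:
    """Canonical integrated diagnostic string for a cluster + grade.

    Grade-IV codeleted tumors are labeled but flagged (no grade IV
    oligodendrogliomas exist as an entity).  2007 oligoastrocytoma
    histology resolves to the cluster-implied entity; the resolution is
    recorded as a warning note.  Unknown grade → NOS suffix.
    """
    cluster = ClusterLabel(cluster)
    warns: list[str] = []
    if grade not in ("II", "III", "IV"):
        label = f"{_BASE_ENTITY[cluster]}, NOS-grade-unknown"
        return IntegratedDiagnosis(cluster, "unknown", label, warns)
    entity = _ENTITY[(cluster, grade)]
    label = f"{entity}, WHO grade {grade}"
    if cluster is ClusterLabel.OLIGO_IDHmut_CODEL and grade == "IV":
        warns.append("grade IV assigned to codeleted cluster: no WHO grade IV oligodendrogliomas")
    if histology_2007 in ("OA", "AOA"):
        warns.append(f"2007 histology {histology_2007} resolved to: {entity}")
    return IntegratedDiagnosis(cluster, grade, label, warns)


def integrated_labels(assignments: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Join cluster assignments with clinical grades → label table."""
    merged = assignments.merge(
        clinical[["sample_id", "who_grade", "histology_2007"]], on="sample_id", how="left"
    )
    merged["who_grade"] = merged["who_grade"].fillna("unknown")
    merged["histology_2007"] = merged["histology_2007"].fillna("unknown")
    rows = []
    for _, r in merged.iterrows():
        diag = integrated_label(ClusterLabel(r["cluster"]), r["who_grade"], r["histology_2007"])
        rows.append(
            {
                "sample_id": r["sample_id"],
                "cluster": r["cluster"],
                "who_grade": diag.grade,
                "integrated_diagnosis": diag.label,
                "warnings": "; ".join(diag.warnings),
            }
        )
    return pd.DataFrame(rows)


def cluster_composition(
    assignments: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency tables: cluster × 2007 histology and cluster × grade."""
    merged = assignments.merge(clinical, on="sample_id", how="left")
    if merged.empty:
        empty = pd.DataFrame()
        return empty, empty.copy()
    by_hist = pd.crosstab(merged["cluster"], merged["histology_2007"])
    by_grade = pd.crosstab(merged["cluster"], merged["who_grade"])
    return by_hist, by_grade
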