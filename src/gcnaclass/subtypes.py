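"""Rule-based prognostic CNA subtypes within the astrocytic clusters.

IDH-wildtype tumors split into W1–W4 on chromosome 1 gain, chromosome 19
gain, and CDK4/MDM2 co-amplification; IDH-mutant tumors split into M1–M3
on CDK4 amplification, CDKN2A homozygous deletion, and chromosome 14
gain.  The branch structure is a declarative ordered rule table
(first-match wins, mandatory catch-all), overridable from YAML without
code changes.  The A/B/C wildtype subgrouping follows its own fixed rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
import yaml

from .cna import CnaCallSet
from .clusters import ClusterLabel


class SubtypeLabel(str, Enum):
    W1 = "W1"
    W2 = "W2"
    W3 = "W3"
    W4 = "W4"
    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    OLIGO_NA = "OLIGO_NA"


class WildtypeSubgroup(str, Enum):
    A = "A"
    B = "B"
    C = "C"


@dataclass
class Rule:
    """Conjunction of flag requirements → label.  Empty conditions = catch-all."""

    conditions: dict[str, bool]
    label: SubtypeLabel

    def matches(self, flags: dict[str, bool | None]) -> bool:
        for name, wanted in self.conditions.items():
            value = flags.get(name)
            if value is None:
                raise ValueError(f"flag {name!r} unresolved; cannot evaluate rule table")
            if bool(value) != wanted:
                return False
        return True

    def flag_names(self) -> set[str]:
        return set(self.conditions)


@dataclass
class RuleTable:
    """Ordered first-match rule list; the last rule must be a catch-all."""

    rules: list[Rule]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("empty rule table")
        if self.rules[-1].conditions:
            raise ValueError(f"rule table {self.name!r} lacks a final catch-all rule")

    def classify(self, flags: dict[str, bool | None]) -> SubtypeLabel:
        missing = sorted(
            n for r in self.rules for n in r.flag_names() if flags.get(n) is None
        )
        if missing:
            raise ValueError(f"missing marker flag(s): {missing}")
        for rule in self.rules:
            if rule.matches(flags):
                return rule.label
        raise AssertionError("unreachable: catch-all guarantees a match")

    def flag_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.rules:
            for n in r.conditions:
                if n not in seen:
                    seen.append(n)
        return seen

    def is_total(self) -> bool:
        """Exhaustively enumerate all flag combinations; each must match
        exactly one first rule (guaranteed by ordered evaluation + catch-all,
        checked by brute force)."""
        from itertools import product

        names = self.flag_names()
        for combo in product([False, True], repeat=len(names)):
            flags = dict(zip(names, combo))
            n_match = sum(r.matches(flags) for r in self.rules)
            if n_match < 1:
                return False
        return True


def default_wildtype_rules() -> RuleTable:
    # documented default, not a verbatim published tree: co-amplification
    # overrides, then chr1 gain, then chr19 gain, catch-all W2
    return RuleTable(
        rules=[
            Rule({"cdk4_mdm2_coamp": True}, SubtypeLabel.W4),
            Rule({"chr1_gain": True}, SubtypeLabel.W1),
            Rule({"chr19_gain": True}, SubtypeLabel.W3),
            Rule({}, SubtypeLabel.W2),
        ],
        name="wildtype",
    )


def default_mutant_rules() -> RuleTable:
    return RuleTable(
        rules=[
            Rule({"cdk4_amp": True}, SubtypeLabel.M1),
            Rule({"cdkn2a_homodel": True}, SubtypeLabel.M1),
            Rule({"chr14_gain": True}, SubtypeLabel.M2),
            Rule({}, SubtypeLabel.M3),
        ],
        name="mutant",
    )


@dataclass
class RuleTables:
    wildtype: RuleTable = field(default_factory=default_wildtype_rules)
    mutant: RuleTable = field(default_factory=default_mutant_rules)


def load_rule_tables(path: str) -> RuleTables:
    """Read rule tables from YAML.

    Format::

        wildtype:
          - when: {cdk4_mdm2_coamp: true}
            label: W4
          - label: W2          # catch-all (no 'when')
        mutant:
          - ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    tables = {}
    for key in ("wildtype", "mutant"):
        entries = doc.get(key)
        if not entries:
            raise ValueError(f"rules file missing table {key!r}")
        rules = [
            Rule(
                {k: bool(v) for k, v in (e.get("when") or {}).items()},
                SubtypeLabel(e["label"]),
            )
            for e in entries
        ]
        tables[key] = RuleTable(rules, name=key)
    return RuleTables(wildtype=tables["wildtype"], mutant=tables["mutant"])


def subgroup_wildtype(chr1_gain: bool, tp53_mut: bool, chr19_gain: bool) -> WildtypeSubgroup:
    """A/B/C wildtype subgroup: A on chr1 gain or TP53 mutation; else B on
    chr19 gain; else C."""
    for name, v in (("chr1_gain", chr1_gain), ("tp53_mut", tp53_mut), ("chr19_gain", chr19_gain)):
        if v is None:
            raise ValueError(f"flag {name} unresolved")
    if chr1_gain or tp53_mut:
        return WildtypeSubgroup.A
    if chr19_gain:
        return WildtypeSubgroup.B
    return WildtypeSubgroup.C


def classify_wildtype(calls: CnaCallSet, table: RuleTable | None = None) -> SubtypeLabel:
    table = table or default_wildtype_rules()
    return table.classify(calls.flags)


def classify_mutant(calls: CnaCallSet, table: RuleTable | None = None) -> SubtypeLabel:
    table = table or default_mutant_rules()
    return table.classify(calls.flags)


def subtype_cohort(
    clusters: pd.DataFrame,
    callsets: list[CnaCallSet],
    mutations: pd.DataFrame | None = None,
    rule_tables: RuleTables | None = None,
) -> pd.DataFrame:
    """Per-sample subtype table: cluster dispatch over the rule tables.

    Codeleted-cluster samples get OLIGO_NA; wildtype samples also get the
    A/B/C subgroup (TP53 status from the mutation table, required for the
    subgroup only).
    """
    rule_tables = rule_tables or RuleTables()
    cluster_by_sample = dict(zip(clusters["sample_id"], clusters["cluster"]))
    tp53_by_sample: dict[str, bool] = {}
    if mutations is not None:
        tp53 = mutations[mutations["gene"] == "TP53"]["sample_id"].unique()
        tp53_by_sample = {s: True for s in tp53}
    rows = []
    for cs in callsets:
        cl = cluster_by_sample.get(cs.sample_id)
        if cl is None:
            raise ValueError(f"sample {cs.sample_id!r} has no cluster label")
        cl = ClusterLabel(cl)
        subgroup = ""
        if cl is ClusterLabel.OLIGO_IDHmut_CODEL:
            subtype = SubtypeLabel.OLIGO_NA
        elif cl is ClusterLabel.ASTRO_IDHmut:
            subtype = classify_mutant(cs, rule_tables.mutant)
        else:
            subtype = classify_wildtype(cs, rule_tables.wildtype)
            if mutations is not None:
                subgroup = subgroup_wildtype(
                    cs.flags.get("chr1_gain"),
                    tp53_by_sample.get(cs.sample_id, False),
                    cs.flags.get("chr19_gain"),
                ).value
        rows.append(
            {
                "sample_id": cs.sample_id,
                "cluster": cl.value,
                "subtype": subtype.value,
                "subgroup": subgroup,
            }
        )
    return pd.DataFrame(rows)
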