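"""Clinical actionability tiering (OncoKB-style levels, ESCAT tiers).

The knowledge content is data, not code: a prostate-cancer-oriented rules
table maps (gene, alteration class, origin constraint) to an evidence
level under each framework, with a therapy label.  The shipped fixture
(``data/synthetic_actionability_rules.tsv``) is a synthetic, editable approximation
of the public OncoKB / ESCAT content for prostate cancer — HRR-gene
loss-of-function and MSI at the top levels, PI3K/AKT-pathway alterations
lower — since both knowledge bases evolve over time.

OncoKB levels are ordered 1 > 2 > 3A > 3B > 4; ESCAT tiers I > II > III >
IV.  OncoKB level-4 matches (compelling preclinical evidence only) are
recorded but never count as clinically actionable.  Heterozygous
deletions match no loss-of-function rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .variants import Alteration, Impact, Origin, PATHOGENIC_SET

ONCOKB = "ONCOKB"
ESCAT = "ESCAT"

#: evidence levels per framework, best first.
LEVEL_ORDER: dict[str, tuple[str, ...]] = {
    ONCOKB: ("1", "2", "3A", "3B", "4"),
    ESCAT: ("I", "II", "III", "IV"),
}

#: OncoKB levels excluded from "clinically actionable".
NON_ACTIONABLE_LEVELS: dict[str, frozenset[str]] = {
    ONCOKB: frozenset({"4"}),
    ESCAT: frozenset(),
}

RULE_CLASSES = ("LOF_SNV", "HOMDEL", "AMP", "FUSION", "MSI")


class RuleValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ActionabilityRule:
    gene: str
    alteration_class: str
    origin: str  # somatic / germline / any
    framework: str
    level: str
    therapy: str


@dataclass(frozen=True)
class PatientActionability:
    patient_id: str
    matches: tuple[tuple[ActionabilityRule, Alteration], ...]
    highest: dict[str, str | None]  # framework -> best actionable level or None
    germline_actionable: bool


def load_rules(path=None) -> list[ActionabilityRule]:
    """Load and validate the rules table (TSV with columns gene,
    alteration_class, origin, framework, level, therapy).  Defaults to the
    packaged fixture.  Duplicate (gene, class, framework) rows and unknown
    levels/classes are rejected with the offending row number."""
    if path is None:
        with resources.as_file(
            resources.files("ctdna_profiler").joinpath(
                "data/synthetic_actionability_rules.tsv"
            )
        ) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "alteration_class", "origin", "framework", "level", "therapy"}
    missing = required - set(df.columns)
    if missing:
        raise RuleValidationError(f"rules table missing columns: {sorted(missing)}")
    rules: list[ActionabilityRule] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        fw = row.framework
        if fw not in LEVEL_ORDER:
            raise RuleValidationError(f"row {i}: unknown framework {fw!r}")
        if row.level not in LEVEL_ORDER[fw]:
            raise RuleValidationError(f"row {i}: unknown level {row.level!r} for {fw}")
        if row.alteration_class not in RULE_CLASSES:
            raise RuleValidationError(
                f"row {i}: unknown alteration class {row.alteration_class!r}"
            )
        if row.origin not in ("somatic", "germline", "any"):
            raise RuleValidationError(f"row {i}: unknown origin {row.origin!r}")
        key = (row.gene, row.alteration_class, fw)
        if key in seen:
            raise RuleValidationError(f"row {i}: duplicate rule for {key}")
        seen.add(key)
        rules.append(ActionabilityRule(row.gene, row.alteration_class, row.origin,
                                       fw, row.level, row.therapy))
    return rules


def _alteration_matches(rule: ActionabilityRule, alt: Alteration) -> bool:
    if rule.gene != alt.gene:
        return False
    if rule.origin == "somatic" and alt.origin is Origin.GERMLINE:
        return False
    if rule.origin == "germline" and alt.origin is not Origin.GERMLINE:
        return False
    cls = alt.alteration_class
    if rule.alteration_class == "LOF_SNV":
        return cls in ("SNV", "INDEL") and (
            alt.pathogenicity in PATHOGENIC_SET or alt.impact is Impact.HIGH
        )
    if rule.alteration_class == "FUSION":
        return cls == "SV"
    # HOMDEL / AMP / MSI match their own class exactly; HETDEL matches nothing.
    return rule.alteration_class == cls


def _best_level(framework: str, levels: Iterable[str]) -> str | None:
    order = LEVEL_ORDER[framework]
    actionable = [l for l in levels if l not in NON_ACTIONABLE_LEVELS[framework]]
    if not actionable:
        return None
    return min(actionable, key=order.index)


def annotate_actionability(
    patient_id: str,
    alterations: Sequence[Alteration],
    rules: Sequence[ActionabilityRule],
    msi_positive: bool = False,
) -> PatientActionability:
    """Match a patient's alterations against the rules table.

    ``msi_positive`` injects the sample-level MSI biomarker as a
    pseudo-alteration so MSI rules can fire.  The per-framework highest
    level is over actionable matches only (OncoKB level 4 excluded).
    """
    alts = list(alterations)
    if msi_positive:
        alts.append(Alteration(gene="MSI", alteration_class="SNV"))
    matches: list[tuple[ActionabilityRule, Alteration]] = []
    for rule in rules:
        for alt in alts:
            if rule.alteration_class == "MSI":
                if msi_positive and alt.gene == "MSI":
                    matches.append((rule, alt))
                    break
            elif _alteration_matches(rule, alt):
                matches.append((rule, alt))
    highest = {
        fw: _best_level(fw, [r.level for r, _ in matches if r.framework == fw])
        for fw in LEVEL_ORDER
    }
    germline_actionable = any(
        a.origin is Origin.GERMLINE
        and r.level not in NON_ACTIONABLE_LEVELS[r.framework]
        for r, a in matches
    )
    return PatientActionability(
        patient_id=patient_id,
        matches=tuple(matches),
        highest=highest,
        germline_actionable=germline_actionable,
    )


def cohort_actionability_summary(
    patients: Sequence[PatientActionability],
) -> pd.DataFrame:
    """Distribution of highest actionable level per framework ('none' for
    unmatched patients), plus the germline-actionable fraction.  Proportions
    sum to 1 within each framework."""
    if not patients:
        raise RuleValidationError("summary requires at least one patient")
    rows = []
    for fw, order in LEVEL_ORDER.items():
        categories = [l for l in order if l not in NON_ACTIONABLE_LEVELS[fw]] + ["none"]
        counts = {c: 0 for c in categories}
        for p in patients:
            counts[p.highest.get(fw) or "none"] += 1
        for level in categories:
            rows.append(
                {
                    "framework": fw,
                    "level": level,
                    "n": counts[level],
                    "proportion": counts[level] / len(patients),
                }
            )
    rows.append(
        {
            "framework": "germline",
            "level": "actionable",
            "n": sum(p.germline_actionable for p in patients),
            "proportion": sum(p.germline_actionable for p in patients) / len(patients),
        }
    )
    return pd.DataFrame(rows)
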